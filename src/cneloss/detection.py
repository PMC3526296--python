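"""Classify CNE presence/loss/missing per species from syntenic flank evidence.

A complete loss of a CNE in a species is called only when the absence of
aligning sequence is embedded in a syntenic alignment of the CNE's flanks and
survives three artifact filters:

1. aligning flanks exist upstream and downstream and are co-syntenic (one
   query scaffold, consistent order and orientation);
2. the region between the aligning flanks contains no assembly gap in the
   query species;
3. the CNE sequence has no similarity hit anywhere in that species' genome or
   its unassembled sequencing reads (traces) — such a hit could mean an
   assembly/alignment error or a translocated element.

Anything short of a clean call is MISSING with a single machine-readable
reason code; MISSING claims neither loss nor conservation. The module also
summarises deletion involvement (reference vs query inter-flank distances),
validates loss regions with single spanning reads, and samples size-matched
control regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CNERecord, _merge, _overlaps
from .phylo import Phylogeny, Role, Status

__all__ = [
    "AlignmentEvidence",
    "LossCall",
    "StatusMatrix",
    "classify_status",
    "build_status_matrix",
    "deletion_analysis",
    "validate_with_traces",
    "sample_control_regions",
]

# MISSING reason codes (precedence order for loss-search species)
NO_FLANK = "no_flank"
NOT_COSYNTENIC = "not_cosyntenic"
ASSEMBLY_GAP = "assembly_gap"
SIMILARITY_HIT = "similarity_hit"
LOW_COVERAGE = "low_coverage_species"

EVIDENCE_COLUMNS = [
    "cne_id",
    "species",
    "ref_chrom",
    "up_ref_start",
    "up_ref_end",
    "down_ref_start",
    "down_ref_end",
    "query_scaffold",
    "up_q_start",
    "up_q_end",
    "down_q_start",
    "down_q_end",
    "strand",
    "cne_overlap_bp",
]


@dataclass
class AlignmentEvidence:
    """Flank alignment evidence for one (CNE, species) pair.

    Flank blocks are reference intervals with their aligned query intervals;
    either flank may be absent (None). ``cne_overlap_bp`` is the number of
    query-aligned bases overlapping the CNE itself.
    """

    cne_id: str
    species: str
    ref_chrom: str
    up_ref: tuple[int, int] | None
    down_ref: tuple[int, int] | None
    query_scaffold: str | None
    up_q: tuple[int, int] | None
    down_q: tuple[int, int] | None
    strand: str  # "+" | "-"
    cne_overlap_bp: int = 0

    @property
    def has_both_flanks(self) -> bool:
        return None not in (self.up_ref, self.down_ref, self.up_q, self.down_q)

    @property
    def co_syntenic(self) -> bool:
        """Both flanks on one scaffold, order/orientation consistent."""
        if not self.has_both_flanks or not self.query_scaffold:
            return False
        if self.strand == "+":
            return self.up_q[1] <= self.down_q[0]
        if self.strand == "-":
            return self.down_q[1] <= self.up_q[0]
        return False

    @property
    def ref_flank_distance(self) -> int | None:
        if not self.has_both_flanks:
            return None
        return self.down_ref[0] - self.up_ref[1]

    @property
    def query_flank_distance(self) -> int | None:
        """Inter-flank distance along the query, after orienting minus-strand
        blocks so the distance is non-negative for co-syntenic flanks."""
        if not self.co_syntenic:
            return None
        if self.strand == "+":
            return self.down_q[0] - self.up_q[1]
        return self.up_q[0] - self.down_q[1]

    @property
    def query_interflank(self) -> tuple[str, int, int] | None:
        """The query interval between the flanks (scaffold, start, end)."""
        if not self.co_syntenic:
            return None
        if self.strand == "+":
            return (self.query_scaffold, self.up_q[1], self.down_q[0])
        return (self.query_scaffold, self.down_q[1], self.up_q[0])

    @classmethod
    def from_row(cls, row: Mapping) -> "AlignmentEvidence":
        def iv(a, b):
            if pd.isna(row.get(a)) or pd.isna(row.get(b)):
                return None
            return (int(row[a]), int(row[b]))

        scaf = row.get("query_scaffold")
        return cls(
            cne_id=str(row["cne_id"]),
            species=str(row["species"]),
            ref_chrom=str(row["ref_chrom"]),
            up_ref=iv("up_ref_start", "up_ref_end"),
            down_ref=iv("down_ref_start", "down_ref_end"),
            query_scaffold=None if pd.isna(scaf) else str(scaf),
            up_q=iv("up_q_start", "up_q_end"),
            down_q=iv("down_q_start", "down_q_end"),
            strand=str(row.get("strand", "+")),
            cne_overlap_bp=int(row.get("cne_overlap_bp", 0) or 0),
        )


@dataclass
class LossCall:
    """Classification of one (CNE, species) cell with its audit trail."""

    cne_id: str
    species: str
    status: Status
    reason: str | None = None  # set iff status is MISSING
    filters_passed: frozenset[str] = frozenset()  # {"flanks","no_gap","no_similarity"}
    trace_validation: str = "not_applicable"
    evidence: AlignmentEvidence | None = None


def classify_status(
    cne: CNERecord,
    species: str,
    role: Role,
    ev: AlignmentEvidence | None,
    gaps: Sequence[tuple[int, int]] | Mapping[str, Sequence[tuple[int, int]]] = (),
    has_similarity_hit: bool = False,
    min_overlap: int = 1,
) -> LossCall:
    """Classify one CNE x species cell.

    CONSERVED if the aligned overlap with the CNE is at least ``min_overlap``
    bp (default 1: any aligning CNE sequence counts as presence). For
    loss-search species with zero overlap, LOST only if co-syntenic flanks
    exist, the query inter-flank interval intersects no assembly gap, and no
    similarity hit is recorded; otherwise MISSING with the first failing
    reason (no_flank -> not_cosyntenic -> assembly_gap -> similarity_hit).
    Presence-only and outgroup species with zero overlap are
    MISSING(low_coverage_species). ``gaps`` is either an interval list on the
    evidence's query scaffold or a scaffold -> intervals mapping.
    """
    if ev is not None and ev.cne_id != cne.id:
        raise ValueError(f"evidence for {ev.cne_id!r} passed with CNE {cne.id!r}")
    if ev is not None and ev.cne_overlap_bp >= min_overlap:
        return LossCall(cne.id, species, Status.CONSERVED, evidence=ev)
    if role != Role.LOSS_SEARCH:
        return LossCall(cne.id, species, Status.MISSING, LOW_COVERAGE, evidence=ev)
    if ev is None or not ev.has_both_flanks:
        return LossCall(cne.id, species, Status.MISSING, NO_FLANK, evidence=ev)
    if not ev.co_syntenic:
        return LossCall(cne.id, species, Status.MISSING, NOT_COSYNTENIC, evidence=ev)
    passed = {"flanks"}
    scaf, s, e = ev.query_interflank
    if isinstance(gaps, Mapping):
        gap_ivs = gaps.get(scaf, ())
    else:
        gap_ivs = gaps
    if _overlaps(s, e, _merge(gap_ivs)):
        return LossCall(
            cne.id, species, Status.MISSING, ASSEMBLY_GAP,
            frozenset(passed), evidence=ev,
        )
    passed.add("no_gap")
    if has_similarity_hit:
        # the element may survive elsewhere (translocation) or the assembly
        # may be wrong: neither loss nor orthologous conservation is claimed
        return LossCall(
            cne.id, species, Status.MISSING, SIMILARITY_HIT,
            frozenset(passed), evidence=ev,
        )
    passed.add("no_similarity")
    return LossCall(cne.id, species, Status.LOST, None, frozenset(passed), evidence=ev)


@dataclass
class StatusMatrix:
    """Complete CNE x species status matrix with reason codes and calls."""

    statuses: pd.DataFrame  # index cne_id, columns species, values Status str
    reasons: pd.DataFrame  # same shape; "" where not MISSING
    calls: dict[tuple[str, str], LossCall]
    dropped: list[str]  # CNEs without a conserved outgroup, excluded

    def status_vector(self, cne_id: str) -> dict[str, Status]:
        return {
            sp: Status(v) for sp, v in self.statuses.loc[cne_id].items()
        }

    def summary(self) -> pd.DataFrame:
        out = {}
        for sp in self.statuses.columns:
            vc = self.statuses[sp].value_counts()
            out[sp] = {s.value: int(vc.get(s.value, 0)) for s in Status}
        return pd.DataFrame(out).T


def build_status_matrix(
    cnes: Sequence[CNERecord],
    evidence: pd.DataFrame,
    gaps: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    hits: pd.DataFrame,
    tree: Phylogeny,
    min_overlap: int = 1,
) -> StatusMatrix:
    """Apply :func:`classify_status` across the catalog.

    ``evidence`` follows ``EVIDENCE_COLUMNS``; ``gaps`` maps species ->
    scaffold -> gap intervals; ``hits`` has columns (cne_id, species, source,
    score). CNEs left with no CONSERVED outgroup are dropped with an audit
    entry (the catalog's outgroup filter normally guarantees at least one).
    Duplicate (cne_id, species) evidence rows raise ``ValueError``.
    """
    if len(evidence):
        dup = evidence.duplicated(subset=["cne_id", "species"])
        if dup.any():
            bad = evidence.loc[dup, ["cne_id", "species"]].iloc[0]
            raise ValueError(
                f"duplicate evidence rows for ({bad.cne_id}, {bad.species})"
            )
    ev_map = {
        (str(r.cne_id), str(r.species)): AlignmentEvidence.from_row(r._asdict())
        for r in evidence.itertuples(index=False)
    }
    hit_set = (
        {(str(c), str(s)) for c, s in zip(hits["cne_id"], hits["species"])}
        if len(hits)
        else set()
    )
    species = tree.leaves
    calls: dict[tuple[str, str], LossCall] = {}
    rows = {}
    reason_rows = {}
    for cne in cnes:
        srow = {}
        rrow = {}
        for sp in species:
            call = classify_status(
                cne,
                sp,
                tree.roles[sp],
                ev_map.get((cne.id, sp)),
                gaps.get(sp, {}),
                (cne.id, sp) in hit_set,
                min_overlap,
            )
            calls[(cne.id, sp)] = call
            srow[sp] = call.status.value
            rrow[sp] = call.reason or ""
        rows[cne.id] = srow
        reason_rows[cne.id] = rrow
    statuses = pd.DataFrame.from_dict(rows, orient="index")[species]
    reasons = pd.DataFrame.from_dict(reason_rows, orient="index")[species]
    og = [sp for sp in species if tree.roles[sp] == Role.OUTGROUP]
    keep = statuses[og].eq(Status.CONSERVED.value).any(axis=1)
    dropped = list(statuses.index[~keep])
    return StatusMatrix(statuses[keep], reasons[keep], calls, dropped)


def deletion_analysis(calls: Iterable[LossCall]) -> pd.DataFrame:
    """Summarise deletion involvement per species over LOST calls.

    For each species: n, mean/median reference and query inter-flank
    distances, mean/median estimated deletion (reference minus query;
    negative values are insertions and are reported as-is), and the
    least-squares slope/intercept of the reference distance regressed on the
    query distance. Empty input yields an empty table.
    """
    recs = []
    for call in calls:
        if call.status != Status.LOST or call.evidence is None:
            continue
        ev = call.evidence
        if ev.query_flank_distance is None:
            continue
        recs.append(
            {
                "species": call.species,
                "ref": float(ev.ref_flank_distance),
                "query": float(ev.query_flank_distance),
            }
        )
    if not recs:
        return pd.DataFrame(
            columns=[
                "species", "n", "ref_mean", "ref_median", "query_mean",
                "query_median", "deletion_mean", "deletion_median",
                "slope", "intercept",
            ]
        ).set_index("species")
    df = pd.DataFrame(recs)
    out = []
    for sp, g in df.groupby("species", sort=True):
        d = g["ref"] - g["query"]
        if len(g) >= 2 and g["query"].nunique() > 1:
            slope, intercept = np.polyfit(g["query"], g["ref"], 1)
        elif (g["query"] == g["ref"]).all():
            slope, intercept = 1.0, 0.0  # identity case, degenerate fit
        else:
            slope, intercept = math.nan, math.nan
        out.append(
            {
                "species": sp,
                "n": len(g),
                "ref_mean": g["ref"].mean(),
                "ref_median": g["ref"].median(),
                "query_mean": g["query"].mean(),
                "query_median": g["query"].median(),
                "deletion_mean": d.mean(),
                "deletion_median": d.median(),
                "slope": float(slope),
                "intercept": float(intercept),
            }
        )
    return pd.DataFrame(out).set_index("species")


def validate_with_traces(
    region: tuple[int, int],
    reads: Iterable[tuple[int, int]],
    flank_pad: int = 50,
    max_len: int = 500,
) -> str:
    """Validate an assembly region with a single spanning sequencing read.

    ``"too_long"`` if the region is ``max_len`` bp or longer (Sanger traces
    average ~800 bp, so only regions strictly under 500 bp are testable);
    ``"validated"`` iff a single read covers the whole region plus
    ``flank_pad`` bp on either side; ``"not_validated"`` otherwise — two
    reads each covering half do not count. Read mapping criteria (identity,
    length, best hit) are applied upstream; this consumes placements.
    """
    if flank_pad < 0 or max_len < 0:
        raise ValueError("flank_pad and max_len must be non-negative")
    start, end = region
    if end - start >= max_len:
        return "too_long"
    lo, hi = start - flank_pad, end + flank_pad
    for rs, re in reads:
        if rs <= lo and re >= hi:
            return "validated"
    return "not_validated"


def sample_control_regions(
    size: int,
    chrom_sizes: Mapping[str, int],
    gaps: Mapping[str, Sequence[tuple[int, int]]],
    n: int = 5,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, int, int]]:
    """Sample ``n`` gap-free control intervals of exactly ``size`` bp.

    Placement is exactly uniform over all feasible start positions on the
    supplied chromosomes/scaffolds (pass only those carrying a loss region):
    feasible segments are computed by interval arithmetic, so no rejection
    loop is needed and the draw is reproducible under a seed. Raises
    ``ValueError`` when no placement exists.
    """
    if size < 0:
        raise ValueError("size must be non-negative")
    rng = np.random.default_rng(rng)
    segments: list[tuple[str, int, int]] = []  # (chrom, first_start, n_starts)
    for chrom, clen in sorted(chrom_sizes.items()):
        limit = clen - size
        if limit < 0:
            continue
        merged = _merge(gaps.get(chrom, ()))
        # starts s where [s, s+size) misses all gaps: subtract the forbidden
        # window [gs-size+1, ge) around each gap from [0, limit]; a
        # zero-length region overlaps nothing
        forbidden = (
            _merge([(max(0, gs - size + 1), ge) for gs, ge in merged])
            if size > 0
            else []
        )
        cur = 0
        for fs, fe in forbidden:
            if fs > limit:
                break
            if fs > cur:
                segments.append((chrom, cur, min(fs, limit + 1) - cur))
            cur = max(cur, fe)
        if cur <= limit:
            segments.append((chrom, cur, limit + 1 - cur))
    total = sum(ns for _, _, ns in segments)
    if total == 0:
        raise ValueError(
            f"no gap-free placement of a {size} bp region on the supplied "
            "chromosomes"
        )
    counts = np.cumsum([ns for _, _, ns in segments])
    out = []
    for u in rng.integers(0, total, size=n):
        i = int(np.searchsorted(counts, u, side="right"))
        chrom, first, _ = segments[i]
        offset = int(u) - (int(counts[i - 1]) if i else 0)
        s = first + offset
        out.append((chrom, s, s + size))
    return out
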