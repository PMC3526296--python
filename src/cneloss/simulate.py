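"""Synthetic input bundles with known ground truth for the CNE-loss pipeline.

The generator works at the coordinate/evidence level — no nucleotide sequence
is simulated. It plants loss events on tree branches with probability
proportional to branch length (neutral substitutions per site) times a
per-CNE loss propensity, emits the alignment-evidence, gap, similarity-hit,
trace-read, TSS and ortholog tables the pipeline consumes, and records the
planted truth so that detection and inference can be checked exactly.

The default configuration is the stated world of the analysis it emulates:
seven loss-search mammals (mouse, rat, guinea pig, cow, horse, dog,
elephant), presence-only relatives and two outgroups; ~5-6% of CNEs carry at
least one loss with per-branch loss frequencies around 1%; deletion sizes
lognormal with median ~2.9 kb; about half of the loss regions short enough
(<500 bp between the flanks) to be spanned by an ~800 bp Sanger read.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CNERecord
from .detection import (
    ASSEMBLY_GAP,
    EVIDENCE_COLUMNS,
    LOW_COVERAGE,
    NO_FLANK,
    NOT_COSYNTENIC,
    SIMILARITY_HIT,
)
from .phylo import Phylogeny, Role, Status, parse_tree

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "ArtifactCase",
    "generate_dataset",
    "emit_artifact_cases",
    "DEFAULT_NEWICK",
    "DEFAULT_ROLES",
]

DEFAULT_NEWICK = (
    "(((((((mouse:0.35,rat:0.33)mouse_rat:0.06,kangaroo_rat:0.33)mrk:0.02,"
    "guinea_pig:0.34)rodents:0.03,(human:0.07,rhesus:0.09)primates:0.06)"
    "euarchontoglires:0.02,(cow:0.20,(dog:0.17,horse:0.13)zooamata:0.02)"
    "laurasiatheria:0.02)boreoeutheria:0.01,elephant:0.17)eutheria:0.15,"
    "(opossum:0.36,platypus:0.46)outgroups:0.10)root;"
)

DEFAULT_ROLES: dict[str, str] = {
    "mouse": "loss_search",
    "rat": "loss_search",
    "guinea_pig": "loss_search",
    "cow": "loss_search",
    "horse": "loss_search",
    "dog": "loss_search",
    "elephant": "loss_search",
    "kangaroo_rat": "presence_only",
    "human": "presence_only",
    "rhesus": "presence_only",
    "opossum": "outgroup",
    "platypus": "outgroup",
}

_FLANK_W = 150  # width of emitted flank blocks, bp


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults emulate the analysed data."""

    seed: int
    n_cnes: int = 2000
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 40_000_000}
    )
    # element length: 70 + lognormal, giving median ~190 bp, mean ~235 bp
    cne_len_log_mu: float = math.log(120.0)
    cne_len_log_sigma: float = 0.8
    newick: str = DEFAULT_NEWICK
    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    # per-branch loss probability = base_loss_rate * branch_length * propensity
    base_loss_rate: float = 0.03
    propensity: str = "uniform"  # "uniform" | "hotspot" | "gamma"
    hotspot_fraction: float = 0.10
    hotspot_fold: float = 10.0
    gamma_shape: float = 2.0
    # per-role missing-data probability per species per CNE
    missing_rate_loss_search: float = 0.02
    missing_rate_presence_only: float = 0.15
    missing_rate_outgroup: float = 0.10
    correlated_missing: bool = False  # whole-scaffold missingness per species
    # deletion sizes: lognormal, median ~2870 bp, mean ~6.3 kb
    deletion_log_mu: float = math.log(2870.0)
    deletion_log_sigma: float = 1.26
    # residual unaligned query between flanks: exponential, ~63% under 500 bp
    query_residual_scale: float = 500.0
    # extra per-cell rates of planted detection artifacts (become MISSING)
    artifact_gap_rate: float = 0.0
    artifact_hit_rate: float = 0.0
    trace_read_length: int = 800
    n_genes: int | None = None  # default n_cnes // 10
    gene_absent_rate: float = 0.02
    gene_gap_rate: float = 0.01
    # constraint/ancestry annotations; hotspot CNEs optionally biased to be
    # shorter, less constrained and younger
    constraint_beta: tuple[float, float] = (4.0, 5.6)
    ancestry_fraction: float = 0.25
    bias_hotspot_characteristics: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        rates = [
            self.missing_rate_loss_search,
            self.missing_rate_presence_only,
            self.missing_rate_outgroup,
            self.artifact_gap_rate,
            self.artifact_hit_rate,
            self.hotspot_fraction,
            self.gene_absent_rate,
            self.gene_gap_rate,
            self.ancestry_fraction,
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must be in [0, 1]")
        if self.hotspot_fold < 1:
            raise ValueError("hotspot fold must be >= 1")
        if (
            self.propensity == "hotspot"
            and self.hotspot_fraction == 0
            and self.hotspot_fold > 1
        ):
            raise ValueError("hotspot fraction 0 with fold > 1 is infeasible")
        if self.propensity not in ("uniform", "hotspot", "gamma"):
            raise ValueError(f"unknown propensity model {self.propensity!r}")
        if self.base_loss_rate < 0:
            raise ValueError("base_loss_rate must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth, consistent with the emitted evidence tables."""

    propensity: dict[str, float]  # cne_id -> multiplier
    events: dict[str, frozenset[str]]  # cne_id -> planted loss branches
    statuses: pd.DataFrame  # cne_id x species truth status
    missing_reasons: dict[tuple[str, str], str]
    deletion_sizes: dict[tuple[str, str], int]  # (cne_id, species) -> bp
    branch_counts: dict[str, int]  # branch -> planted event count

    def to_jsonable(self) -> dict:
        return {
            "propensity": self.propensity,
            "events": {k: sorted(v) for k, v in self.events.items()},
            "statuses": {
                cid: dict(row) for cid, row in self.statuses.iterrows()
            },
            "missing_reasons": {
                f"{c}|{s}": r for (c, s), r in self.missing_reasons.items()
            },
            "deletion_sizes": {
                f"{c}|{s}": d for (c, s), d in self.deletion_sizes.items()
            },
            "branch_counts": self.branch_counts,
        }


@dataclass
class SyntheticDataset:
    """One complete, internally consistent input bundle."""

    config: GeneratorConfig
    tree: Phylogeny
    newick: str
    roles: dict[str, str]
    cnes: list[CNERecord]
    evidence: pd.DataFrame
    gaps: dict[str, dict[str, list[tuple[int, int]]]]
    hits: pd.DataFrame
    traces: dict[str, dict[str, list[tuple[int, int]]]]
    tss: pd.DataFrame
    orthologs: pd.DataFrame
    truth: SyntheticTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.config.chrom_sizes)

    def cne_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.cnes],
                "chrom": [c.chrom for c in self.cnes],
                "start": [c.start for c in self.cnes],
                "end": [c.end for c in self.cnes],
                "constraint_rs": [c.constraint_rs for c in self.cnes],
                "phylop_p": [c.phylop_p for c in self.cnes],
                "ancestry_pre_mammal": [c.ancestry_pre_mammal for c in self.cnes],
            }
        )

    def write(self, outdir: str) -> None:
        """Emit the bundle as plain-text BED/TSV/Newick/JSON files."""
        os.makedirs(outdir, exist_ok=True)
        cf = self.cne_frame()
        cf[["chrom", "start", "end", "id"]].to_csv(
            os.path.join(outdir, "cnes.bed"), sep="\t", header=False, index=False
        )
        cf.to_csv(os.path.join(outdir, "cne_annotations.tsv"), sep="\t", index=False)
        self.evidence.to_csv(
            os.path.join(outdir, "evidence.tsv"), sep="\t", index=False
        )
        self.hits.to_csv(os.path.join(outdir, "hits.tsv"), sep="\t", index=False)
        for label, tracks in (("gaps", self.gaps), ("traces", self.traces)):
            d = os.path.join(outdir, label)
            os.makedirs(d, exist_ok=True)
            for sp, scafs in tracks.items():
                rows = [
                    (scaf, s, e)
                    for scaf, ivs in sorted(scafs.items())
                    for s, e in sorted(ivs)
                ]
                pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
                    os.path.join(d, f"{sp}.bed"), sep="\t", header=False, index=False
                )
        self.tss.to_csv(os.path.join(outdir, "tss.bed"), sep="\t", index=False)
        self.orthologs.to_csv(
            os.path.join(outdir, "orthologs.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.newick + "\n")
        with open(os.path.join(outdir, "roles.json"), "w") as fh:
            json.dump(self.roles, fh, indent=1, sort_keys=True)
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth.to_jsonable(), fh, indent=1, sort_keys=True)


# ----------------------------------------------------------------- generator


def _planted_branches(tree: Phylogeny) -> list[str]:
    """Branches the generator plants losses on: every leaf below is a
    loss-search species, so the loss is observable without forced missing
    data."""
    ls = tree.role_mask[Role.LOSS_SEARCH]
    return sorted(
        tree.names[i]
        for i in range(len(tree.names))
        if i != tree.root and tree.leaf_mask[i] & ~ls == 0
    )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full input bundle plus its ground truth.

    Loss events are drawn per CNE and branch with probability
    ``base_loss_rate * branch_length * propensity``, then the branch set
    (with the CNE's missing-data mask) is rejected and redrawn until the
    planted events are exactly re-inferable by parsimony — the round-trip
    guarantee every downstream test relies on.
    """
    rng = np.random.default_rng(config.seed)
    tree = parse_tree(config.newick, config.roles)
    species = tree.leaves
    role_of = {sp: tree.roles[sp] for sp in species}
    missing_rate = {
        Role.LOSS_SEARCH: config.missing_rate_loss_search,
        Role.PRESENCE_ONLY: config.missing_rate_presence_only,
        Role.OUTGROUP: config.missing_rate_outgroup,
    }
    outgroups = [sp for sp in species if role_of[sp] == Role.OUTGROUP]

    # --- propensities
    n = config.n_cnes
    if config.propensity == "uniform":
        prop = np.ones(n)
        hot = np.zeros(n, dtype=bool)
    elif config.propensity == "hotspot":
        hot = rng.random(n) < config.hotspot_fraction
        prop = np.where(hot, config.hotspot_fold, 1.0)
    else:  # gamma, mean 1
        prop = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=n)
        hot = prop > np.quantile(prop, 0.9)

    # --- coordinates and annotations
    lengths = (
        70 + np.exp(rng.normal(config.cne_len_log_mu, config.cne_len_log_sigma, n))
    ).astype(int)
    if config.bias_hotspot_characteristics:
        lengths = np.where(hot, 70 + ((lengths - 70) * 0.5).astype(int), lengths)
    chroms = sorted(config.chrom_sizes)
    total = sum(config.chrom_sizes.values())
    counts = {
        c: max(1, int(round(n * config.chrom_sizes[c] / total))) for c in chroms
    }
    while sum(counts.values()) != n:  # fix rounding drift
        c = chroms[0] if sum(counts.values()) < n else max(counts, key=counts.get)
        counts[c] += 1 if sum(counts.values()) < n else -1
    rs = rng.beta(*config.constraint_beta, size=n)
    anc = rng.random(n) < config.ancestry_fraction
    if config.bias_hotspot_characteristics:
        rs = np.where(hot, np.clip(rs - 0.08, 0.0, 1.0), rs)
        anc = np.where(hot & (rng.random(n) < 0.5), False, anc)
    phylop = 10.0 ** (-rng.uniform(5, 40, size=n))
    cnes: list[CNERecord] = []
    i = 0
    for c in chroms:
        k = counts[c]
        slot = config.chrom_sizes[c] // k
        for j in range(k):
            length = int(lengths[i])
            if slot <= length + 2000:
                raise ValueError(
                    f"chromosome {c} too small for {k} CNEs of this length"
                )
            start = j * slot + 1000 + int(rng.integers(0, slot - length - 2000))
            cnes.append(
                CNERecord(
                    f"cne{i:05d}",
                    c,
                    start,
                    start + length,
                    float(rs[i]),
                    float(phylop[i]),
                    bool(anc[i]),
                )
            )
            i += 1

    # --- plant loss events + missing masks, enforcing re-inferability
    branches = _planted_branches(tree)
    b_ids = [tree.branch_id(b) for b in branches]
    b_masks = [tree.leaf_mask[i] for i in b_ids]
    b_len = np.array([tree.branch_length[i] for i in b_ids])
    p_branch = np.minimum(1.0, config.base_loss_rate * b_len)
    sp_bits = {sp: 1 << tree.leaf_index[sp] for sp in species}
    scaffold_missing = {
        sp: (
            config.correlated_missing
            and rng.random() < missing_rate[role_of[sp]]
        )
        for sp in species
    }
    events: dict[str, frozenset[str]] = {}
    missing_sets: dict[str, set[str]] = {}
    infer = tree.infer_masks
    for idx, cne in enumerate(cnes):
        pi = prop[idx]
        for _ in range(200):
            draw = rng.random(len(branches)) < np.minimum(1.0, p_branch * pi)
            chosen = [k for k in range(len(branches)) if draw[k]]
            lost_mask = 0
            for k in chosen:
                lost_mask |= b_masks[k]
            ids = frozenset(b_ids[k] for k in chosen)
            if not chosen:
                break
            if infer(lost_mask, 0) == ids:
                break
        else:
            chosen, ids, lost_mask = [], frozenset(), 0
        for _ in range(200):
            miss: set[str] = set()
            mmask = 0
            for sp in species:
                bit = sp_bits[sp]
                if bit & lost_mask:
                    continue
                p_m = missing_rate[role_of[sp]]
                hit_m = (
                    scaffold_missing[sp]
                    if config.correlated_missing
                    else rng.random() < p_m
                )
                if role_of[sp] == Role.LOSS_SEARCH and rng.random() < (
                    config.artifact_gap_rate + config.artifact_hit_rate
                ):
                    hit_m = True
                if hit_m:
                    miss.add(sp)
                    mmask |= bit
            if all(sp in miss for sp in outgroups):
                continue  # keep >=1 conserved outgroup
            if not chosen or infer(lost_mask, mmask) == ids:
                break
        else:
            miss, mmask = set(), 0
        events[cne.id] = frozenset(branches[k] for k in chosen)
        missing_sets[cne.id] = miss

    # --- emit evidence and side tables
    ev_rows = []
    gaps: dict[str, dict[str, list[tuple[int, int]]]] = {
        sp: {} for sp in species
    }
    traces: dict[str, dict[str, list[tuple[int, int]]]] = {
        sp: {} for sp in species
    }
    hit_rows = []
    missing_reasons: dict[tuple[str, str], str] = {}
    deletion_sizes: dict[tuple[str, str], int] = {}
    status_rows: dict[str, dict[str, str]] = {}
    loss_reason_choices = [NO_FLANK, NOT_COSYNTENIC, ASSEMBLY_GAP, SIMILARITY_HIT]

    for idx, cne in enumerate(cnes):
        lost_mask = 0
        for b in events[cne.id]:
            lost_mask |= tree.leaf_mask[tree.branch_id(b)]
        srow = {}
        for sp in species:
            bit = sp_bits[sp]
            scaf = f"{cne.chrom}_{sp}"
            strand = "+" if rng.random() < 0.9 else "-"
            qbase = cne.start  # simple 1:1 query coordinate frame
            if sp in missing_sets[cne.id]:
                srow[sp] = Status.MISSING.value
                if role_of[sp] != Role.LOSS_SEARCH:
                    missing_reasons[(cne.id, sp)] = LOW_COVERAGE
                    continue  # no evidence row at all
                reason = loss_reason_choices[int(rng.integers(0, 4))]
                missing_reasons[(cne.id, sp)] = reason
                if reason == NO_FLANK:
                    continue
                qd = int(rng.exponential(config.query_residual_scale)) + 1
                row = _loss_row(cne, sp, scaf, strand, qd, qd, qbase)
                if reason == NOT_COSYNTENIC:
                    row["strand"] = "."
                elif reason == ASSEMBLY_GAP:
                    s, e = row["_inner"]
                    mid = (s + e) // 2
                    gaps[sp].setdefault(scaf, []).append((mid, min(e, mid + 25) + 1))
                elif reason == SIMILARITY_HIT:
                    hit_rows.append(
                        {
                            "cne_id": cne.id,
                            "species": sp,
                            "source": "trace" if rng.random() < 0.5 else "genome",
                            "score": int(rng.integers(40, 200)),
                        }
                    )
                row.pop("_inner")
                ev_rows.append(row)
            elif bit & lost_mask:
                srow[sp] = Status.LOST.value
                delta = int(
                    np.exp(rng.normal(config.deletion_log_mu, config.deletion_log_sigma))
                )
                delta = max(delta, cne.length + 100)
                qd = int(rng.exponential(config.query_residual_scale)) + 1
                deletion_sizes[(cne.id, sp)] = delta
                row = _loss_row(cne, sp, scaf, strand, delta + qd, qd, qbase)
                s, e = row.pop("_inner")
                if qd < 500:  # spanning Sanger read validates the region
                    pad = config.trace_read_length - (e - s) - 100
                    lo = s - 50 - max(0, int(rng.integers(0, max(1, pad))))
                    traces[sp].setdefault(scaf, []).append(
                        (max(0, lo), max(0, lo) + config.trace_read_length)
                    )
                ev_rows.append(row)
            else:
                srow[sp] = Status.CONSERVED.value
                up_q = (qbase - 50 - _FLANK_W, qbase - 50)
                down_q = (qbase + cne.length + 50, qbase + cne.length + 50 + _FLANK_W)
                if strand == "-":
                    up_q, down_q = down_q, up_q
                ev_rows.append(
                    {
                        "cne_id": cne.id,
                        "species": sp,
                        "ref_chrom": cne.chrom,
                        "up_ref_start": cne.start - 50 - _FLANK_W,
                        "up_ref_end": cne.start - 50,
                        "down_ref_start": cne.end + 50,
                        "down_ref_end": cne.end + 50 + _FLANK_W,
                        "query_scaffold": scaf,
                        "up_q_start": up_q[0],
                        "up_q_end": up_q[1],
                        "down_q_start": down_q[0],
                        "down_q_end": down_q[1],
                        "strand": strand,
                        "cne_overlap_bp": cne.length,
                    }
                )
        status_rows[cne.id] = srow

    evidence = pd.DataFrame(ev_rows, columns=EVIDENCE_COLUMNS)
    hits = pd.DataFrame(hit_rows, columns=["cne_id", "species", "source", "score"])

    # --- genes: TSS positions and ortholog presence
    n_genes = config.n_genes or max(10, n // 10)
    grows = []
    loss_search = [sp for sp in species if role_of[sp] == Role.LOSS_SEARCH]
    orows = []
    for g in range(n_genes):
        c = chroms[g % len(chroms)]
        pos = int(rng.integers(0, config.chrom_sizes[c]))
        gid = f"gene{g:04d}"
        grows.append(
            {
                "chrom": c,
                "pos": pos,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_id": gid,
            }
        )
        for sp in loss_search:
            u = rng.random()
            if u < config.gene_absent_rate:
                status = "absent"
            elif u < config.gene_absent_rate + config.gene_gap_rate:
                status = "gap"
            else:
                status = "present"
            orows.append({"gene_id": gid, "species": sp, "status": status})
    tss = pd.DataFrame(grows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    orthologs = pd.DataFrame(orows)

    statuses = pd.DataFrame.from_dict(status_rows, orient="index")[species]
    branch_counts: dict[str, int] = {b: 0 for b in branches}
    for ev in events.values():
        for b in ev:
            branch_counts[b] += 1
    truth = SyntheticTruth(
        propensity={c.id: float(prop[i]) for i, c in enumerate(cnes)},
        events=events,
        statuses=statuses,
        missing_reasons=missing_reasons,
        deletion_sizes=deletion_sizes,
        branch_counts=branch_counts,
    )
    return SyntheticDataset(
        config=config,
        tree=tree,
        newick=config.newick,
        roles=dict(config.roles),
        cnes=cnes,
        evidence=evidence,
        gaps=gaps,
        hits=hits,
        traces=traces,
        tss=tss,
        orthologs=orthologs,
        truth=truth,
    )


def _loss_row(
    cne: CNERecord,
    sp: str,
    scaf: str,
    strand: str,
    ref_dist: int,
    query_dist: int,
    qbase: int,
) -> dict:
    """Evidence row for a zero-overlap cell with co-syntenic flanks.

    The reference inter-flank distance is ``ref_dist`` (deleted span plus
    unaligned residue) and the query inter-flank distance is ``query_dist``.
    Returns the row dict plus the query inter-flank interval under ``_inner``.
    """
    u = min(max(50, (ref_dist - cne.length) // 2), max(50, cne.start - _FLANK_W))
    up_ref_end = cne.start - u
    up_ref_start = up_ref_end - _FLANK_W
    down_ref_start = up_ref_end + ref_dist
    down_ref_end = down_ref_start + _FLANK_W
    if strand in ("+", "."):
        up_q = (qbase - _FLANK_W, qbase)
        down_q = (qbase + query_dist, qbase + query_dist + _FLANK_W)
        inner = (qbase, qbase + query_dist)
        if strand == ".":
            # declare '-' orientation but keep the '+' block layout: a '-'
            # mapping needs the downstream block before the upstream one in
            # query coordinates, so this is not co-syntenic
            strand = "-"
            inner = (0, 0)
    else:
        down_q = (qbase - _FLANK_W, qbase)
        up_q = (qbase + query_dist, qbase + query_dist + _FLANK_W)
        inner = (qbase, qbase + query_dist)
    return {
        "cne_id": cne.id,
        "species": sp,
        "ref_chrom": cne.chrom,
        "up_ref_start": max(0, up_ref_start),
        "up_ref_end": max(_FLANK_W, up_ref_end),
        "down_ref_start": down_ref_start,
        "down_ref_end": down_ref_end,
        "query_scaffold": scaf,
        "up_q_start": up_q[0],
        "up_q_end": up_q[1],
        "down_q_start": down_q[0],
        "down_q_end": down_q[1],
        "strand": strand,
        "cne_overlap_bp": 0,
        "_inner": inner,
    }


# ------------------------------------------------------------ labeled cases


@dataclass
class ArtifactCase:
    """A deterministic mini-fixture with its expected classification."""

    name: str
    cne: CNERecord
    species: str
    role: Role
    evidence: dict | None  # EVIDENCE_COLUMNS row, or None
    gaps: list[tuple[int, int]]
    has_hit: bool
    expected_status: Status
    expected_reason: str | None


def emit_artifact_cases(config: GeneratorConfig | None = None) -> list[ArtifactCase]:
    """One labeled fixture per detection filter.

    Cases: a clean loss (all filters pass); an assembly-gap mimic; a
    translocated element with a trace hit; a missing flank; inconsistent
    flank orientation; a low-coverage species absence; and a conserved
    control. Deterministic — no randomness involved.
    """
    cne = CNERecord("case", "chr1", 10_000, 10_200)

    def loss_row(strand="+", qd=300):
        r = _loss_row(cne, "mouse", "chr1_mouse", strand, 2000 + qd, qd, cne.start)
        r.pop("_inner")
        return r

    no_down = loss_row()
    for col in ("down_ref_start", "down_ref_end", "down_q_start", "down_q_end"):
        no_down[col] = np.nan
    swapped = _loss_row(cne, "mouse", "chr1_mouse", ".", 2300, 300, cne.start)
    swapped.pop("_inner")
    conserved = loss_row()
    conserved["cne_overlap_bp"] = cne.length
    inner = (cne.start, cne.start + 300)
    return [
        ArtifactCase(
            "clean_loss", cne, "mouse", Role.LOSS_SEARCH, loss_row(), [], False,
            Status.LOST, None,
        ),
        ArtifactCase(
            "assembly_gap_mimic", cne, "mouse", Role.LOSS_SEARCH, loss_row(),
            [(inner[0] + 100, inner[0] + 150)], False,
            Status.MISSING, ASSEMBLY_GAP,
        ),
        ArtifactCase(
            "translocated_trace_hit", cne, "mouse", Role.LOSS_SEARCH, loss_row(),
            [], True, Status.MISSING, SIMILARITY_HIT,
        ),
        ArtifactCase(
            "missing_flank", cne, "mouse", Role.LOSS_SEARCH, no_down, [], False,
            Status.MISSING, NO_FLANK,
        ),
        ArtifactCase(
            "inconsistent_orientation", cne, "mouse", Role.LOSS_SEARCH, swapped,
            [], False, Status.MISSING, NOT_COSYNTENIC,
        ),
        ArtifactCase(
            "low_coverage_absence", cne, "human", Role.PRESENCE_ONLY, None, [],
            False, Status.MISSING, LOW_COVERAGE,
        ),
        ArtifactCase(
            "conserved_control", cne, "mouse", Role.LOSS_SEARCH, conserved, [],
            False, Status.CONSERVED, None,
        ),
    ]
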