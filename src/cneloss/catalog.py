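"""Build the analyzable CNE catalog from candidate conserved elements.

Candidate elements (e.g. PhastCons most-conserved regions) pass a battery of
inclusion filters before any loss is called on them:

* minimum length (default 70 bp) after trimming;
* no overlap with coding exons, and trimming of any portion within 100 bp of
  an exon flank (conserved splicing signals);
* no overlap with ncRNAs, pseudogenes or transposons;
* no protein similarity (Blastx best E-value < 0.01 rejects);
* no close paralog in the reference (second-best self-BLAT score >= 40
  rejects — such regions are prone to misalignment of orthologs);
* alignment to at least one outgroup species, which establishes that the
  element is ancestral rather than recently gained;
* reference chromosomes on a deny-list (mitochondrial, random, haplotype)
  are excluded.

Hit tables are inputs: this package never runs Blastx/BLAT itself; an absent
entry means no hit. Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CNERecord",
    "FilterThresholds",
    "FilterReport",
    "apply_cne_filters",
    "flag_ancestry",
    "select_highly_conserved",
]

# reason codes, in audit precedence order
REASON_DENY_CHROM = "deny_chromosome"
REASON_EXON = "exon_overlap"
REASON_NCRNA = "ncrna_transposon_pseudogene_overlap"
REASON_LENGTH = "min_length"
REASON_BLASTX = "blastx_hit"
REASON_BLAT = "self_blat_hit"
REASON_OUTGROUP = "no_outgroup_alignment"


@dataclass
class CNERecord:
    """One conserved non-coding element in reference coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    constraint_rs: float | None = None  # GERP fraction of rejected substitutions
    phylop_p: float | None = None  # phyloP conservation P-value
    ancestry_pre_mammal: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.constraint_rs is not None and not 0 <= self.constraint_rs <= 1:
            raise ValueError(f"constraint_rs {self.constraint_rs} outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class FilterThresholds:
    """Catalog inclusion thresholds; defaults are the published values."""

    min_length: int = 70  # keep only elements >= this long (after trimming)
    blastx_evalue: float = 0.01  # E < this rejects (protein similarity)
    blat_second_score: int = 40  # second self-BLAT hit score >= this rejects
    exon_flank: int = 100  # trim element portions within this of exon flanks
    deny_chromosomes: tuple[str, ...] = ("chrM",)
    deny_substrings: tuple[str, ...] = ("_random", "_hap")

    def __post_init__(self) -> None:
        if min(self.min_length, self.exon_flank) < 0 or self.blastx_evalue < 0:
            raise ValueError("thresholds must be non-negative")

    def chrom_denied(self, chrom: str) -> bool:
        return chrom in self.deny_chromosomes or any(
            s in chrom for s in self.deny_substrings
        )


@dataclass
class FilterReport:
    """Per-candidate audit: every input element appears exactly once."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_accepted(self) -> int:
        return int(self.rows["accepted"].sum())

    @property
    def n_rejected(self) -> int:
        return int((~self.rows["accepted"]).sum())


# ----------------------------------------------------------- interval helpers


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps(start: int, end: int, merged: Sequence[tuple[int, int]]) -> bool:
    if not merged:
        return False
    starts = [s for s, _ in merged]
    i = np.searchsorted(starts, end, side="left")
    return i > 0 and merged[i - 1][1] > start


def _subtract(start: int, end: int, merged: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """The parts of [start, end) not covered by the merged intervals."""
    out = []
    cur = start
    for s, e in merged:
        if e <= cur:
            continue
        if s >= end:
            break
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < end:
        out.append((cur, end))
    return out


def _by_chrom(track: Iterable[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in track:
        per.setdefault(chrom, []).append((s, e))
    return {c: _merge(ivs) for c, ivs in per.items()}


# ------------------------------------------------------------------- filters


def apply_cne_filters(
    candidates: Iterable[CNERecord],
    exon_track: Iterable[tuple[str, int, int]] = (),
    ncrna_transposon_pseudogene_track: Iterable[tuple[str, int, int]] = (),
    blastx_hits: Mapping[str, float] | None = None,
    self_blat_hits: Mapping[str, float] | None = None,
    outgroup_alignment: Mapping[str, Iterable[str]] | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[CNERecord], FilterReport]:
    """Apply the catalog inclusion filters and return accepted elements + audit.

    Elements overlapping an exon or the ncRNA/transposon/pseudogene track are
    rejected outright. Surviving elements have any portion within
    ``exon_flank`` bp of an exon flank trimmed away; trimming may split an
    element, and every resulting fragment re-enters the length filter
    independently (fragment ids get ``.1``, ``.2`` suffixes). ``blastx_hits``
    maps element id to its best (minimum) Blastx E-value;
    ``self_blat_hits`` maps id to the second-best self-BLAT score;
    ``outgroup_alignment`` maps id to the set of outgroup species the element
    aligns to. Absent entries mean no hit / no alignment.
    """
    th = thresholds or FilterThresholds()
    blastx_hits = dict(blastx_hits or {})
    self_blat_hits = dict(self_blat_hits or {})
    outgroup_alignment = {
        k: set(v) for k, v in (outgroup_alignment or {}).items()
    }
    exons = _by_chrom(exon_track)
    nc = _by_chrom(ncrna_transposon_pseudogene_track)
    # exon flank zones: exon_flank bp on each side of each exon, exon excluded
    flank_zones: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in exons.items():
        zones = []
        for s, e in ivs:
            zones.append((max(0, s - th.exon_flank), s))
            zones.append((e, e + th.exon_flank))
        flank_zones[chrom] = _merge(zones)

    accepted: list[CNERecord] = []
    audit_rows = []

    def audit(cne: CNERecord, ok: bool, reason: str | None, trimmed: str = "") -> None:
        audit_rows.append(
            {
                "id": cne.id,
                "chrom": cne.chrom,
                "start": cne.start,
                "end": cne.end,
                "accepted": ok,
                "reason": reason or "",
                "trimmed_to": trimmed,
            }
        )

    seen: set[str] = set()
    for cne in candidates:
        if cne.id in seen:
            raise ValueError(f"duplicate candidate id {cne.id!r}")
        seen.add(cne.id)
        if th.chrom_denied(cne.chrom):
            audit(cne, False, REASON_DENY_CHROM)
            continue
        if _overlaps(cne.start, cne.end, exons.get(cne.chrom, ())):
            audit(cne, False, REASON_EXON)
            continue
        if _overlaps(cne.start, cne.end, nc.get(cne.chrom, ())):
            audit(cne, False, REASON_NCRNA)
            continue
        fragments = _subtract(cne.start, cne.end, flank_zones.get(cne.chrom, ()))
        fragments = [(s, e) for s, e in fragments if e - s >= th.min_length]
        if not fragments:
            audit(cne, False, REASON_LENGTH)
            continue
        if blastx_hits.get(cne.id, np.inf) < th.blastx_evalue:
            audit(cne, False, REASON_BLASTX)
            continue
        if self_blat_hits.get(cne.id, -np.inf) >= th.blat_second_score:
            audit(cne, False, REASON_BLAT)
            continue
        if not outgroup_alignment.get(cne.id):
            audit(cne, False, REASON_OUTGROUP)
            continue
        split = len(fragments) > 1
        whole = fragments == [(cne.start, cne.end)]
        for j, (s, e) in enumerate(fragments, start=1):
            frag_id = cne.id if whole else (f"{cne.id}.{j}" if split else cne.id)
            flags = cne.flags if whole else cne.flags + ("trimmed",)
            accepted.append(
                CNERecord(
                    frag_id,
                    cne.chrom,
                    s,
                    e,
                    cne.constraint_rs,
                    cne.phylop_p,
                    cne.ancestry_pre_mammal,
                    flags,
                )
            )
        audit(
            cne,
            True,
            None,
            "" if whole else ";".join(f"{s}-{e}" for s, e in fragments),
        )

    report = FilterReport(pd.DataFrame(audit_rows))
    return accepted, report


def flag_ancestry(
    cne: CNERecord, nonmammal_alignment_cov: Mapping[str, int], min_fraction: float = 0.80
) -> bool:
    """Whether the element predates the mammalian ancestor.

    True iff it aligns with at least ``min_fraction`` (default 80%, inclusive)
    of its length to any non-mammalian vertebrate in the supplied coverage
    table (aligned bp per species: chicken, zebra finch, lizard, frog, fish).
    """
    for sp, cov in nonmammal_alignment_cov.items():
        if cov > cne.length:
            raise ValueError(
                f"coverage {cov} for {sp!r} exceeds element length {cne.length}"
            )
        if cov / cne.length >= min_fraction:
            return True
    return False


def select_highly_conserved(
    cnes: Iterable[CNERecord],
    rs_min: float = 0.5,
    phylop_max: float = 1e-20,
) -> list[CNERecord]:
    """Extremely conserved subset: GERP RS fraction strictly > ``rs_min`` and
    phyloP P strictly < ``phylop_max`` (both thresholds as printed sources
    state them, strict). Elements missing either annotation are skipped with
    a warning.
    """
    out = []
    skipped = 0
    for cne in cnes:
        if cne.constraint_rs is None or cne.phylop_p is None:
            skipped += 1
            continue
        if cne.constraint_rs > rs_min and cne.phylop_p < phylop_max:
            out.append(cne)
    if skipped:
        warnings.warn(
            f"select_highly_conserved: skipped {skipped} element(s) without "
            "constraint_rs/phylop_p annotation",
            stacklevel=2,
        )
    return out
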