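"""Genomic-context analyses of independently lost CNEs.

Groups the catalog by loss history (no loss / lineage-specific / independent),
scans for windows with unusually many independently lost CNEs, verifies that
clustered losses are separate events rather than one large deletion, asks
whether independent losses track losses of the nearest gene, and compares
length, constraint and ancestry between size-matched groups — the proxies for
regulatory pleiotropy.
"""

from __future__ import annotations

import collections
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

from .catalog import CNERecord
from .detection import StatusMatrix
from .phylo import Phylogeny, Role, Status

__all__ = [
    "CneGroupLabel",
    "group_cnes",
    "window_clusters",
    "verify_separate_events",
    "assign_nearest_tss",
    "gene_loss_association",
    "size_matched_sample",
    "compare_characteristics",
]

GROUPS = ("no_loss", "lineage_specific", "independent")


@dataclass(frozen=True)
class CneGroupLabel:
    group: str  # one of GROUPS
    k: int  # independent multiplicity; 0 unless group == "independent"


def group_cnes(
    events_per_cne: Mapping[str, Iterable[str]]
) -> dict[str, CneGroupLabel]:
    """Partition CNEs by loss history: 0 branches -> no_loss, 1 ->
    lineage_specific, >=2 -> independent with multiplicity k."""
    out = {}
    for cid, ev in events_per_cne.items():
        k = len(set(ev))
        if k == 0:
            out[cid] = CneGroupLabel("no_loss", 0)
        elif k == 1:
            out[cid] = CneGroupLabel("lineage_specific", 0)
        else:
            out[cid] = CneGroupLabel("independent", k)
    return out


def window_clusters(
    independent_cnes: Iterable[tuple[str, float]],
    chrom_sizes: Mapping[str, int],
    window: int = 5_000_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window counts of independently lost CNEs, ranked.

    ``independent_cnes`` yields (chrom, position) pairs (use midpoints).
    Windows of ``window`` bp start every ``step`` bp from 0 and are clipped
    at chromosome ends. Returns a DataFrame (chrom, start, end, count, rank)
    sorted by count descending; tied counts share a rank.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    if not chrom_sizes:
        raise ValueError("empty genome")
    per: dict[str, list[float]] = collections.defaultdict(list)
    for chrom, pos in independent_cnes:
        per[chrom].append(pos)
    rows = []
    for chrom, size in sorted(chrom_sizes.items()):
        pos = np.sort(per.get(chrom, []))
        if pos.size == 0:
            continue
        n_starts = max(1, -(-max(0, size - window) // step) + 1)
        starts = np.arange(n_starts) * step
        ends = np.minimum(starts + window, size)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        for s, e, c in zip(starts, ends, hi - lo):
            if c > 0:
                rows.append({"chrom": chrom, "start": int(s), "end": int(e), "count": int(c)})
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "count", "rank"])
    df = pd.DataFrame(rows).sort_values(
        ["count", "chrom", "start"], ascending=[False, True, True]
    )
    counts = df["count"].to_numpy()
    # competition ranking: ties share the rank of their first member
    df["rank"] = [int(1 + (counts > c).sum()) for c in counts]
    return df.reset_index(drop=True)


def verify_separate_events(
    cnes: Sequence[CNERecord],
    matrix: StatusMatrix,
    species_pair: tuple[str, str],
) -> tuple[pd.DataFrame, bool]:
    """Check that adjacent CNEs lost in both species are separate events.

    ``cnes`` must be on one chromosome and sorted by position. For each
    adjacent pair of CNEs lost in both species of the pair, reports True iff
    at least one intervening CNE is CONSERVED in both species — i.e. the two
    losses cannot stem from one deletion spanning both. Returns the
    per-adjacent-pair table and an ``all separate`` flag.
    """
    chroms = {c.chrom for c in cnes}
    if len(chroms) > 1:
        raise ValueError("all CNEs must be on one chromosome")
    starts = [c.start for c in cnes]
    if starts != sorted(starts):
        raise ValueError("CNEs must be sorted by position")
    a, b = species_pair

    def lost_in_both(c: CNERecord) -> bool:
        row = matrix.statuses.loc[c.id]
        return row[a] == Status.LOST.value and row[b] == Status.LOST.value

    def conserved_in_both(c: CNERecord) -> bool:
        row = matrix.statuses.loc[c.id]
        return (
            row[a] == Status.CONSERVED.value and row[b] == Status.CONSERVED.value
        )

    lost_idx = [i for i, c in enumerate(cnes) if lost_in_both(c)]
    rows = []
    for i, j in zip(lost_idx, lost_idx[1:]):
        separated = any(conserved_in_both(cnes[m]) for m in range(i + 1, j))
        rows.append(
            {
                "left": cnes[i].id,
                "right": cnes[j].id,
                "separated": separated,
            }
        )
    table = pd.DataFrame(rows, columns=["left", "right", "separated"])
    all_sep = bool(table["separated"].all()) if len(table) else True
    return table, all_sep


def assign_nearest_tss(
    cnes: Sequence[CNERecord],
    tss: pd.DataFrame,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Assign each CNE to the nearest transcription start site.

    ``tss`` needs columns (chrom, pos, strand, gene_id). Distance is measured
    from the CNE midpoint (or closest edge with ``anchor="edge"``) to the TSS
    position, orientation-independently — enhancers act on either side of a
    promoter. Nearest by absolute distance; exact ties break toward the
    smaller TSS coordinate and are flagged. Returns (cne_id, gene_id,
    distance) with signed distance = TSS - anchor.
    """
    if tss.empty:
        raise ValueError("empty TSS list")
    if anchor not in ("midpoint", "edge"):
        raise ValueError(f"unknown anchor {anchor!r}")
    rows = []
    by_chrom = {
        chrom: g.sort_values(["pos", "gene_id"]).reset_index(drop=True)
        for chrom, g in tss.groupby("chrom")
    }
    for cne in cnes:
        g = by_chrom.get(cne.chrom)
        if g is None or g.empty:
            rows.append(
                {"cne_id": cne.id, "gene_id": None, "distance": np.nan, "tie": False}
            )
            continue
        pos = g["pos"].to_numpy()
        if anchor == "midpoint":
            dist = pos - cne.midpoint
        else:
            dist = np.where(
                pos < cne.start, pos - cne.start,
                np.where(pos >= cne.end, pos - (cne.end - 1), 0),
            )
        absd = np.abs(dist)
        best = absd.min()
        cand = np.flatnonzero(absd == best)
        tie = len(cand) > 1
        i = cand[np.argmin(pos[cand])]  # tie toward smaller coordinate
        rows.append(
            {
                "cne_id": cne.id,
                "gene_id": g["gene_id"].iloc[i],
                "distance": float(dist[i]),
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)


def gene_loss_association(
    assignments: pd.DataFrame,
    ortholog_presence: pd.DataFrame,
    events_per_cne: Mapping[str, Iterable[str]],
    tree: Phylogeny,
) -> tuple[dict[str, int], pd.DataFrame]:
    """How often the nearest gene is lost in the CNE-loss species.

    ``ortholog_presence`` has columns (gene_id, species, status) with status
    in {present, absent, gap}; 'gap' entries (gene unresolvable due to
    assembly gaps) never count as gene losses. Loss species of a CNE are the
    loss-search leaves below its loss branches. Returns counts
    ``any_species`` (nearest gene absent in >=1 loss species) and
    ``all_species`` (absent in every loss species) plus a per-CNE audit.
    """
    pres = {
        (str(r.gene_id), str(r.species)): str(r.status)
        for r in ortholog_presence.itertuples(index=False)
    }
    ls_mask = tree.role_mask[Role.LOSS_SEARCH]
    audit = []
    any_ct = all_ct = 0
    for row in assignments.itertuples(index=False):
        cid, gene = row.cne_id, row.gene_id
        branches = set(events_per_cne.get(cid, ()))
        if not branches or gene is None:
            continue
        mask = 0
        for b in branches:
            mask |= tree.leaf_mask[tree.branch_id(b)]
        loss_species = sorted(tree.mask_species(mask & ls_mask))
        statuses = {}
        for sp in loss_species:
            try:
                statuses[sp] = pres[(str(gene), sp)]
            except KeyError:
                raise ValueError(
                    f"ortholog table lacks ({gene}, {sp})"
                ) from None
        absent = [sp for sp, s in statuses.items() if s == "absent"]
        in_any = len(absent) >= 1
        in_all = len(absent) == len(loss_species) and in_any
        any_ct += in_any
        all_ct += in_all
        audit.append(
            {
                "cne_id": cid,
                "gene_id": gene,
                "loss_species": ",".join(loss_species),
                "absent_species": ",".join(absent),
                "absent_in_any": in_any,
                "absent_in_all": in_all,
            }
        )
    return {"any_species": any_ct, "all_species": all_ct}, pd.DataFrame(audit)


def size_matched_sample(
    groups: Mapping[str, Sequence[CNERecord]],
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[CNERecord]]:
    """Length-matched no-loss and lineage-specific sets for the independent set.

    For every independently lost CNE, one CNE of exactly the same length is
    drawn without replacement from each other group, so the three sets have
    identical length multisets. Raises ``ValueError`` naming the lengths that
    cannot be matched.
    """
    rng = np.random.default_rng(rng)
    independent = list(groups["independent"])
    out: dict[str, list[CNERecord]] = {"independent": independent}
    need = collections.Counter(c.length for c in independent)
    for grp in ("no_loss", "lineage_specific"):
        pool: dict[int, list[CNERecord]] = collections.defaultdict(list)
        for c in groups[grp]:
            pool[c.length].append(c)
        unmatched = sorted(
            length for length, cnt in need.items() if len(pool[length]) < cnt
        )
        if unmatched:
            raise ValueError(
                f"group {grp!r} lacks candidates for lengths {unmatched}"
            )
        chosen: list[CNERecord] = []
        for length in sorted(need):
            cands = sorted(pool[length], key=lambda c: c.id)
            idx = rng.choice(len(cands), size=need[length], replace=False)
            chosen.extend(cands[i] for i in sorted(idx))
        out[grp] = chosen
    return out


def compare_characteristics(
    groups: Mapping[str, Sequence[CNERecord]],
    extreme_rs: float = 0.6,
) -> pd.DataFrame:
    """Compare pleiotropy proxies between CNE groups.

    Per group: mean/median length, mean constraint (GERP rejected-substitution
    fraction), fraction extremely constrained (RS > ``extreme_rs``), and
    fraction predating the mammalian ancestor. Pairwise Wilcoxon rank-sum
    P-values for the continuous features and chi-square (2x2, no continuity
    correction) for the proportions. Constant features are skipped with a
    note instead of a test.
    """
    if len(groups) < 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError("need >=2 non-empty groups")
    names = list(groups)
    summ = []
    for gname in names:
        cs = groups[gname]
        rs = np.array([c.constraint_rs for c in cs if c.constraint_rs is not None])
        lengths = np.array([c.length for c in cs])
        anc = np.array([c.ancestry_pre_mammal for c in cs])
        summ.append(
            {
                "group": gname,
                "n": len(cs),
                "length_mean": lengths.mean(),
                "length_median": float(np.median(lengths)),
                "constraint_mean": rs.mean() if rs.size else np.nan,
                "frac_extreme_rs": float((rs > extreme_rs).mean()) if rs.size else np.nan,
                "frac_pre_mammal": float(anc.mean()),
            }
        )
    summary = pd.DataFrame(summ).set_index("group")

    tests = []
    for a, b in itertools.combinations(names, 2):
        ca, cb = groups[a], groups[b]
        for feature, getter in (
            ("length", lambda c: c.length),
            ("constraint_rs", lambda c: c.constraint_rs),
        ):
            xa = np.array([getter(c) for c in ca if getter(c) is not None], float)
            xb = np.array([getter(c) for c in cb if getter(c) is not None], float)
            if xa.size == 0 or xb.size == 0:
                tests.append((a, b, feature, "rank_sum", np.nan, "feature not annotated"))
                continue
            if np.ptp(np.concatenate([xa, xb])) == 0:
                tests.append((a, b, feature, "rank_sum", np.nan, "constant feature"))
                continue
            p = st.ranksums(xa, xb).pvalue
            tests.append((a, b, feature, "rank_sum", p, ""))
        for feature, getter in (
            ("frac_extreme_rs", lambda c: c.constraint_rs is not None and c.constraint_rs > extreme_rs),
            ("frac_pre_mammal", lambda c: c.ancestry_pre_mammal),
        ):
            ka = sum(getter(c) for c in ca)
            kb = sum(getter(c) for c in cb)
            table = np.array([[ka, len(ca) - ka], [kb, len(cb) - kb]])
            if (table.sum(axis=0) == 0).any():
                tests.append((a, b, feature, "chi_square", np.nan, "constant feature"))
                continue
            p = st.chi2_contingency(table, correction=False).pvalue
            tests.append((a, b, feature, "chi_square", p, ""))
    test_df = pd.DataFrame(
        tests, columns=["group_a", "group_b", "feature", "test", "p", "note"]
    )
    return summary, test_df
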