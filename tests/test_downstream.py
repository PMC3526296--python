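"""Grouping, window clustering, TSS assignment, gene-loss association,
size matching and characteristic comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from cneloss.catalog import CNERecord
from cneloss.downstream import (
    assign_nearest_tss,
    compare_characteristics,
    gene_loss_association,
    group_cnes,
    size_matched_sample,
    verify_separate_events,
    window_clusters,
)
from cneloss.phylo import parse_tree


@pytest.fixture(scope="module")
def pair_tree():
    return parse_tree(
        "(((guinea_pig:0.4,dog:0.2)gd:0.1,mouse:0.35)in:0.1,out:0.5)root;",
        {
            "guinea_pig": "loss_search",
            "dog": "loss_search",
            "mouse": "loss_search",
            "out": "outgroup",
        },
    )


class TestGrouping:
    def test_partition(self):
        labels = group_cnes(
            {
                "a": frozenset(),
                "b": frozenset({"mouse_rat"}),
                "c": frozenset({"mouse", "guinea_pig"}),
                "d": frozenset({"mouse", "dog", "cow"}),
            }
        )
        assert labels["a"].group == "no_loss"
        assert labels["b"].group == "lineage_specific"
        assert (labels["c"].group, labels["c"].k) == ("independent", 2)
        assert labels["d"].k == 3


class TestWindowClusters:
    SIZES = {"chrX": 20_000_000}

    def test_empty(self):
        assert window_clusters([], self.SIZES).empty

    def test_planted_cluster_found(self):
        # 3 CNEs within 1 Mb -> a 5 Mb window holds all 3
        pos = [("chrX", 4_000_000), ("chrX", 4_500_000), ("chrX", 4_900_000)]
        df = window_clusters(pos, self.SIZES)
        assert df.iloc[0]["count"] == 3
        assert df.iloc[0]["rank"] == 1

    def test_two_clusters_ranked(self):
        pos = [("chrX", 1_000_000 + i * 10_000) for i in range(4)]
        pos += [("chrX", 15_000_000 + i * 10_000) for i in range(2)]
        df = window_clusters(pos, self.SIZES)
        assert df.iloc[0]["count"] == 4 and df.iloc[0]["rank"] == 1
        two = df[df["count"] == 2]
        assert (two["rank"] > 1).all()

    def test_tiling_counts_sum_to_total(self):
        rng = np.random.default_rng(4)
        pos = [("chrX", int(p)) for p in rng.integers(0, 20_000_000, 57)]
        df = window_clusters(pos, self.SIZES, window=5_000_000, step=5_000_000)
        assert df["count"].sum() == 57

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            window_clusters([], self.SIZES, window=10, step=20)
        with pytest.raises(ValueError, match="empty genome"):
            window_clusters([], {})


class TestSeparateEvents:
    def _matrix(self, tree, statuses):
        from cneloss.detection import StatusMatrix

        df = pd.DataFrame.from_dict(statuses, orient="index")[tree.leaves]
        reasons = df.copy()
        reasons[:] = ""
        return StatusMatrix(df, reasons, {}, [])

    def _cnes(self, n):
        return [CNERecord(f"c{i}", "chrX", 1000 * i, 1000 * i + 100) for i in range(n)]

    def test_lost_conserved_lost_is_separate(self, pair_tree):
        cnes = self._cnes(3)
        sv = lambda gp, d: {
            "guinea_pig": gp, "dog": d, "mouse": "conserved", "out": "conserved"
        }
        m = self._matrix(
            pair_tree,
            {
                "c0": sv("lost", "lost"),
                "c1": sv("conserved", "conserved"),
                "c2": sv("lost", "lost"),
            },
        )
        table, all_sep = verify_separate_events(cnes, m, ("guinea_pig", "dog"))
        assert all_sep and list(table["separated"]) == [True]

    def test_adjacent_losses_not_separate(self, pair_tree):
        cnes = self._cnes(2)
        sv = {"guinea_pig": "lost", "dog": "lost", "mouse": "conserved", "out": "conserved"}
        m = self._matrix(pair_tree, {"c0": dict(sv), "c1": dict(sv)})
        table, all_sep = verify_separate_events(cnes, m, ("guinea_pig", "dog"))
        assert not all_sep

    def test_nine_separated_losses(self, pair_tree):
        """Alternating lost/conserved over 17 CNEs: all 8 adjacent pairs of
        the 9 doubly lost CNEs are separated."""
        statuses = {}
        cnes = self._cnes(17)
        for i in range(17):
            both = "lost" if i % 2 == 0 else "conserved"
            statuses[f"c{i}"] = {
                "guinea_pig": both, "dog": both,
                "mouse": "conserved", "out": "conserved",
            }
        m = self._matrix(pair_tree, statuses)
        table, all_sep = verify_separate_events(cnes, m, ("guinea_pig", "dog"))
        assert len(table) == 8 and all_sep

    def test_unsorted_rejected(self, pair_tree):
        cnes = self._cnes(3)[::-1]
        m = self._matrix(
            pair_tree,
            {f"c{i}": {sp: "conserved" for sp in pair_tree.leaves} for i in range(3)},
        )
        with pytest.raises(ValueError, match="sorted"):
            verify_separate_events(cnes, m, ("guinea_pig", "dog"))


class TestNearestTSS:
    TSS = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [90, 300, 5000],
            "strand": ["+", "-", "+"],
            "gene_id": ["g1", "g2", "g3"],
        }
    )

    def test_nearest_by_midpoint(self):
        cne = CNERecord("a", "chr1", 50, 150)  # midpoint 100
        out = assign_nearest_tss([cne], self.TSS)
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["distance"] == -10

    def test_tie_breaks_to_smaller_coordinate(self):
        cne = CNERecord("a", "chr1", 145, 245)  # midpoint 195: 105 from both
        out = assign_nearest_tss([cne], self.TSS)
        assert out.iloc[0]["gene_id"] == "g1"
        assert bool(out.iloc[0]["tie"])

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(8)
        tss = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": rng.integers(0, 1_000_000, 60),
                "strand": "+",
                "gene_id": [f"g{i}" for i in range(60)],
            }
        )
        cnes = [
            CNERecord(f"c{i}", "chr1", int(s), int(s) + 100)
            for i, s in enumerate(rng.integers(0, 1_000_000, 40))
        ]
        out = assign_nearest_tss(cnes, tss)
        for cne, row in zip(cnes, out.itertuples(index=False)):
            dists = [(abs(p - cne.midpoint), p, g) for p, g in zip(tss["pos"], tss["gene_id"])]
            best = min(dists)
            assert abs(row.distance) == best[0]

    def test_empty_tss_errors(self):
        with pytest.raises(ValueError):
            assign_nearest_tss([CNERecord("a", "chr1", 0, 10)], pd.DataFrame())


class TestGeneLoss:
    def _setup(self, pair_tree, statuses):
        orth = pd.DataFrame(
            [
                {"gene_id": "g1", "species": sp, "status": statuses.get(sp, "present")}
                for sp in ("guinea_pig", "dog", "mouse")
            ]
        )
        assign = pd.DataFrame(
            [{"cne_id": "c0", "gene_id": "g1", "distance": 100.0, "tie": False}]
        )
        events = {"c0": frozenset({"guinea_pig", "dog"})}
        return assign, orth, events

    def test_present_everywhere(self, pair_tree):
        assign, orth, events = self._setup(pair_tree, {})
        counts, audit = gene_loss_association(assign, orth, events, pair_tree)
        assert counts == {"any_species": 0, "all_species": 0}

    def test_absent_in_one(self, pair_tree):
        assign, orth, events = self._setup(pair_tree, {"dog": "absent"})
        counts, _ = gene_loss_association(assign, orth, events, pair_tree)
        assert counts == {"any_species": 1, "all_species": 0}

    def test_absent_in_all(self, pair_tree):
        assign, orth, events = self._setup(
            pair_tree, {"dog": "absent", "guinea_pig": "absent"}
        )
        counts, _ = gene_loss_association(assign, orth, events, pair_tree)
        assert counts == {"any_species": 1, "all_species": 1}

    def test_gap_never_counts_as_loss(self, pair_tree):
        assign, orth, events = self._setup(
            pair_tree, {"dog": "gap", "guinea_pig": "absent"}
        )
        counts, _ = gene_loss_association(assign, orth, events, pair_tree)
        assert counts == {"any_species": 1, "all_species": 0}

    def test_missing_table_entry_errors(self, pair_tree):
        assign, orth, events = self._setup(pair_tree, {})
        orth = orth[orth["species"] != "dog"]
        with pytest.raises(ValueError, match="lacks"):
            gene_loss_association(assign, orth, events, pair_tree)


class TestSizeMatching:
    def _group(self, lengths, prefix):
        return [
            CNERecord(f"{prefix}{i}", "chr1", 0, L, constraint_rs=0.4)
            for i, L in enumerate(lengths)
        ]

    def test_identical_length_multisets(self):
        groups = {
            "independent": self._group([100, 150, 100], "i"),
            "no_loss": self._group([100, 100, 100, 150, 150, 200], "n"),
            "lineage_specific": self._group([150, 100, 100, 300], "l"),
        }
        out = size_matched_sample(groups, rng=3)
        target = sorted(c.length for c in groups["independent"])
        for g in ("no_loss", "lineage_specific"):
            assert sorted(c.length for c in out[g]) == target
            assert len(set(c.id for c in out[g])) == len(out[g])  # no replacement

    def test_unmatched_length_errors(self):
        groups = {
            "independent": self._group([100, 150], "i"),
            "no_loss": self._group([100, 100], "n"),
            "lineage_specific": self._group([150, 100], "l"),
        }
        with pytest.raises(ValueError, match="150"):
            size_matched_sample(groups, rng=0)

    def test_seed_reproducible(self):
        groups = {
            "independent": self._group([100, 150], "i"),
            "no_loss": self._group([100, 150, 100, 150], "n"),
            "lineage_specific": self._group([100, 100, 150, 150], "l"),
        }
        a = size_matched_sample(groups, rng=12)
        b = size_matched_sample(groups, rng=12)
        assert [c.id for c in a["no_loss"]] == [c.id for c in b["no_loss"]]


class TestCompareCharacteristics:
    def _group(self, n, length, rs, anc_frac, prefix, seed=0):
        rng = np.random.default_rng(seed)
        return [
            CNERecord(
                f"{prefix}{i}",
                "chr1",
                0,
                int(length + rng.integers(0, 50)),
                constraint_rs=float(np.clip(rs + rng.normal(0, 0.05), 0, 1)),
                ancestry_pre_mammal=bool(rng.random() < anc_frac),
            )
            for i in range(n)
        ]

    def test_identical_groups_give_high_p(self):
        g = self._group(200, 150, 0.4, 0.25, "a", seed=1)
        summary, tests = compare_characteristics({"x": g, "y": list(g)})
        assert (tests["p"].dropna() > 0.9).all()

    def test_planted_trends_detected(self):
        groups = {
            "no_loss": self._group(400, 240, 0.45, 0.25, "n", seed=2),
            "lineage_specific": self._group(400, 140, 0.41, 0.18, "l", seed=3),
            "independent": self._group(400, 120, 0.38, 0.12, "i", seed=4),
        }
        summary, tests = compare_characteristics(groups)
        # direction: independent CNEs shorter, less constrained, younger
        assert (
            summary.loc["independent", "length_mean"]
            < summary.loc["no_loss", "length_mean"]
        )
        assert (
            summary.loc["independent", "constraint_mean"]
            < summary.loc["no_loss", "constraint_mean"]
        )
        assert (
            summary.loc["independent", "frac_pre_mammal"]
            < summary.loc["no_loss", "frac_pre_mammal"]
        )
        sel = tests[(tests.group_a == "no_loss") & (tests.group_b == "independent")]
        for feature in ("length", "constraint_rs", "frac_pre_mammal"):
            assert float(sel[sel.feature == feature]["p"].iloc[0]) < 0.05

    def test_chi_square_matches_closed_form(self):
        """0.25 vs 0.15 ancestry at n=500 each: classic 2x2 chi-square."""
        a = [
            CNERecord(f"a{i}", "chr1", 0, 100, constraint_rs=0.4,
                      ancestry_pre_mammal=i < 125)
            for i in range(500)
        ]
        b = [
            CNERecord(f"b{i}", "chr1", 0, 100, constraint_rs=0.4,
                      ancestry_pre_mammal=i < 75)
            for i in range(500)
        ]
        _, tests = compare_characteristics({"a": a, "b": b})
        p = float(
            tests[(tests.feature == "frac_pre_mammal")]["p"].iloc[0]
        )
        # closed-form Pearson chi-square on [[125,375],[75,425]]
        table = np.array([[125, 375], [75, 425]])
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - exp) ** 2 / exp).sum()
        p_closed = st.chi2.sf(chi2, 1)
        assert p == pytest.approx(p_closed)
        assert p < 0.01

    def test_ranksum_matches_reference(self):
        """Rank-sum P equals an independent normal-approximation computation."""
        rng = np.random.default_rng(9)
        xa = rng.normal(100, 10, 80)
        xb = rng.normal(110, 10, 80)
        a = [CNERecord(f"a{i}", "chr1", 0, max(2, int(v))) for i, v in enumerate(xa)]
        b = [CNERecord(f"b{i}", "chr1", 0, max(2, int(v))) for i, v in enumerate(xb)]
        _, tests = compare_characteristics({"a": a, "b": b})
        p = float(tests[tests.feature == "length"]["p"].iloc[0])
        la = np.array([c.length for c in a])
        lb = np.array([c.length for c in b])
        ranks = st.rankdata(np.concatenate([la, lb]))
        w = ranks[: len(la)].sum()
        mu = len(la) * (len(la) + len(lb) + 1) / 2
        sigma = np.sqrt(len(la) * len(lb) * (len(la) + len(lb) + 1) / 12)
        z = (w - mu) / sigma
        p_ref = 2 * st.norm.sf(abs(z))
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_constant_feature_skipped(self):
        a = [CNERecord(f"a{i}", "chr1", 0, 100, constraint_rs=0.4) for i in range(10)]
        b = [CNERecord(f"b{i}", "chr1", 0, 100, constraint_rs=0.4) for i in range(10)]
        _, tests = compare_characteristics({"a": a, "b": b})
        row = tests[tests.feature == "length"].iloc[0]
        assert row["note"] == "constant feature" and np.isnan(row["p"])
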