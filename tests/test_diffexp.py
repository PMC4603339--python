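"""Normalization, fold changes, BH and the NB test against oracles."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeoseq import diffexp, synth


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def _toy_design(libs=("w1", "w2", "c1", "c2")):
    return pd.Series({libs[0]: "wild", libs[1]: "wild",
                      libs[2]: "cultivar", libs[3]: "cultivar"})


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(diffexp.size_factors(counts), 1.0)

    def test_doubled_library_splits_geometrically(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = diffexp.size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(51)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 4)),
            columns=["l1", "l2", "l3", "l4"],
        )
        sf = diffexp.size_factors(counts)
        # independent oracle: literal median-of-ratios per library
        for j, lib in enumerate(counts.columns):
            ratios = []
            for _, row in counts.iterrows():
                if (row > 0).all():
                    geo = np.prod(row.to_numpy(dtype=float)) ** (1 / 4)
                    ratios.append(row[lib] / geo)
            assert sf[lib] == pytest.approx(np.median(ratios), rel=1e-12)

    def test_no_common_nonzero_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            diffexp.size_factors(counts)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "mean_wild,mean_other,expected",
        [
            # printed group baseMeans and their published fold changes
            (1093.35, 416.13, -1.39),
            (1093.35, 388.49, -1.49),
            (1933.05, 441.04, -2.13),
            (1933.05, 647.98, -1.58),
            (5610.65, 1515.59, -1.89),
            (5610.65, 1849.21, -1.60),
            (944.48, 181.67, -2.38),
            (944.48, 269.42, -1.81),
            (939.60, 192.99, -2.28),
            (939.60, 304.20, -1.63),
            (42.47, 1189.91, 4.81),
            (42.47, 717.98, 4.08),
        ],
    )
    def test_reproduces_printed_fold_changes(self, mean_wild, mean_other,
                                             expected):
        lfc = diffexp.log2_fold_change(mean_wild, mean_other)
        assert _round2(lfc) == expected

    def test_silent_target_group_is_minus_inf(self):
        assert diffexp.log2_fold_change(177.41, 0.0) == float("-inf")

    def test_silent_reference_group_is_plus_inf(self):
        assert diffexp.log2_fold_change(0.0, 53.86) == float("inf")

    def test_both_silent_is_undefined(self):
        assert np.isnan(diffexp.log2_fold_change(0.0, 0.0))

    def test_equal_means_give_zero(self):
        assert diffexp.log2_fold_change(123.4, 123.4) == 0.0

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert diffexp.log2_fold_change(a, b) == pytest.approx(
            -diffexp.log2_fold_change(b, a), abs=1e-9
        )


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert diffexp.benjamini_hochberg([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        adj = diffexp.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert diffexp.benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx(
            [1.0, 1.0, 1.0]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            diffexp.benjamini_hochberg([0.5, 1.2])

    @given(st.permutations(list(range(8))))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_invariance(self, perm):
        p = np.array([0.001, 0.2, 0.8, 0.04, 0.5, 0.11, 0.03, 0.95])
        adj = diffexp.benjamini_hochberg(p)
        shuffled = diffexp.benjamini_hochberg(p[perm])
        assert np.allclose(adj[perm], shuffled)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(52)
        p = rng.random(100)
        adj = diffexp.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNbTest:
    def test_all_zero_gene_never_significant(self):
        counts = pd.DataFrame(
            {"w1": [0, 10], "w2": [0, 12], "c1": [0, 9], "c2": [0, 11]},
            index=["dead", "alive"],
        )
        p = diffexp.nb_test(counts, _toy_design(), ("cultivar", "wild"),
                            dispersions=0.1)
        assert p["dead"] == 1.0

    def test_missing_contrast_group_rejected(self):
        counts = pd.DataFrame({"w1": [5], "w2": [6], "c1": [5], "c2": [6]})
        with pytest.raises(ValueError, match="absent"):
            diffexp.nb_test(counts, _toy_design(), ("landrace", "wild"))

    def test_scale_invariance_on_proportional_fixture(self):
        # exactly proportional columns: rescaling one library (and letting
        # median-of-ratios re-absorb it) must not move any p-value
        m = np.array([5, 8, 12, 20, 40, 7, 9, 30, 15, 11])
        t = np.array([1, 2, 1, 3])
        counts = pd.DataFrame(
            np.outer(m, t), columns=["w1", "w2", "c1", "c2"],
            index=[f"g{i}" for i in range(10)],
        )
        p1 = diffexp.nb_test(counts, _toy_design(), ("cultivar", "wild"),
                             dispersions=0.0)
        scaled = counts.copy()
        scaled["w2"] *= 3
        p2 = diffexp.nb_test(scaled, _toy_design(), ("cultivar", "wild"),
                             dispersions=0.0)
        assert np.abs(p1.to_numpy() - p2.to_numpy()).max() < 1e-8

    def test_type_i_error_close_to_nominal_with_true_dispersion(self):
        cfg = synth.SimConfig(
            n_genes=2000, nb_dispersion=0.1, mean_expression=(100.0, 100.0),
            rng_seed=7,
        )
        counts, design, _, _ = synth.simulate_counts(cfg)
        p = diffexp.nb_test(counts, design, ("cultivar", "wild"),
                            dispersions=0.1)
        rate = (p < 0.05).mean()
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)  # binomial 99 % CI
        assert abs(rate - 0.05) < ci

    def test_power_on_planted_fourfold_changes(self):
        # |log2FC| = 2 at mean 200, 2+2 replicates, dispersion 0.1
        up = {synth.pair_id(i): 2.0 for i in range(100)}
        cfg = synth.SimConfig(
            n_genes=500, nb_dispersion=0.1, planted_up=up,
            mean_expression=(200.0, 200.0), rng_seed=9,
        )
        counts, design, truth, _ = synth.simulate_counts(cfg)
        p = diffexp.nb_test(counts, design, ("cultivar", "wild"),
                            dispersions=0.1)
        planted = (truth["status"] == "up").to_numpy()
        assert (p[planted] < 0.01).mean() >= 0.8

    def test_planted_fold_changes_recovered(self):
        # median |log2FC| estimate within 0.25 of truth at group mean >= 100
        up, down = synth.auto_plant(400, 50, 50, effect_lfc=2.0)
        cfg = synth.SimConfig(
            n_genes=400, nb_dispersion=0.05, planted_up=up,
            planted_down=down, mean_expression=(100.0, 1000.0), rng_seed=15,
        )
        counts, design, truth, _ = synth.simulate_counts(cfg)
        res = diffexp.de_results(counts, design, ("cultivar", "wild"),
                                 dispersions=0.05)
        planted = truth.index[truth["status"] != "null"]
        err = (res.loc[planted, "log2fc"].abs() - 2.0).abs()
        assert err.median() <= 0.25


class TestCallsAndIntersection:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "log2fc", "p_adj"]
        ).set_index("gene_id")

    def test_threshold_edges(self):
        res = self._frame([
            ("edge", 0.9, 0.001),       # fold change below the cut
            ("weak_p", 2.5, 0.2),       # FDR above the cut
            ("up", 1.0, 0.1),           # both at the boundary (inclusive)
            ("down", -3.0, 0.01),
            ("inf_down", float("-inf"), 0.02),
            ("na", float("nan"), float("nan")),
        ])
        calls = diffexp.call_degs(res)
        assert calls.tolist() == ["NS", "NS", "UP", "DOWN", "DOWN", "NS"]

    def test_direction_consistent_intersection(self):
        res_c = self._frame([
            ("both_up", 2.0, 0.01), ("conflict", 2.0, 0.01),
            ("only_c", 3.0, 0.01), ("both_down", -2.0, 0.01),
        ])
        res_c["call"] = diffexp.call_degs(res_c)
        res_l = self._frame([
            ("both_up", 1.5, 0.02), ("conflict", -2.0, 0.01),
            ("only_c", 0.1, 0.9), ("both_down", -1.2, 0.05),
        ])
        res_l["call"] = diffexp.call_degs(res_l)
        inter, regions = diffexp.domesticated_vs_wild(res_c, res_l)
        assert set(inter.index) == {"both_up", "both_down"}
        assert inter.loc["both_up", "direction"] == "UP"
        assert regions["both_direction_consistent"] == 2
        assert regions["cultivar_only"] == 1

    def test_venn_regions_match_set_oracle(self):
        rng = np.random.default_rng(53)
        genes = [f"g{i}" for i in range(200)]
        rows_c = [(g, rng.choice([-2.0, 0.0, 2.0]), rng.choice([0.01, 0.5]))
                  for g in genes]
        rows_l = [(g, rng.choice([-2.0, 0.0, 2.0]), rng.choice([0.01, 0.5]))
                  for g in genes]
        res_c, res_l = self._frame(rows_c), self._frame(rows_l)
        res_c["call"] = diffexp.call_degs(res_c)
        res_l["call"] = diffexp.call_degs(res_l)
        _, regions = diffexp.domesticated_vs_wild(res_c, res_l)
        set_c = set(res_c.index[res_c["call"] != "NS"])
        set_l = set(res_l.index[res_l["call"] != "NS"])
        assert regions["cultivar_only"] == len(set_c - set_l)
        assert regions["landrace_only"] == len(set_l - set_c)
        assert regions["both"] == len(set_c & set_l)
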