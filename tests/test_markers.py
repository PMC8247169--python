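"""Marker detection, hypergeometric overlap, grids, region comparisons."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from cbstates.core_io import NormMatrix, lognormalize
from cbstates.markers import (
    compare_region_scores,
    filter_state_signature,
    find_markers,
    hypergeometric_overlap,
    intersection_grid,
    profile_correlation,
)
from cbstates.signatures import ScoreMatrix
from cbstates.synthdata import SimConfig, generate_reference_cells


def exact_upper_tail(k, N, K, n):
    """Brute-force exact-integer oracle for P(X >= k), X ~ Hypergeom(N, K, n)."""
    denom = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / denom


class TestHypergeometricOverlap:
    def test_zero_overlap_p_is_one(self):
        bg = {f"g{i}" for i in range(50)}
        k, p = hypergeometric_overlap({"g0", "g1"}, {"g10", "g11"}, bg)
        assert k == 0 and p == 1.0

    def test_forced_overlap_p_is_one(self):
        bg = {f"g{i}" for i in range(30)}
        a = {"g0", "g1", "g2"}
        k, p = hypergeometric_overlap(a, bg, bg)
        assert k == 3 and p == pytest.approx(1.0)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        bg = [f"g{i}" for i in range(100)]
        for _ in range(50):
            a = set(rng.choice(bg, size=10, replace=False))
            b = set(rng.choice(bg, size=20, replace=False))
            k, p = hypergeometric_overlap(a, b, set(bg))
            oracle = exact_upper_tail(k, 100, 10, 20)
            assert p == pytest.approx(oracle, rel=1e-10)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError, match="outside the background"):
            hypergeometric_overlap({"x"}, {"g0"}, {"g0", "g1"})


class TestFindMarkers:
    def test_low_detection_genes_not_tested(self):
        rng = np.random.default_rng(1)
        n = 40
        data = np.zeros((2 * n, 3))
        # gene 0: detected in 20% on both sides but large when present
        hits = rng.choice(n, size=n // 5, replace=False)
        data[hits, 0] = 5.0
        data[n + hits, 0] = 1.0
        data[:, 1] = rng.normal(2, 0.1, 2 * n).clip(0)
        data[:n, 2] = 3.0
        data[n:, 2] = 1.0
        x = NormMatrix(data, np.array([f"c{i}" for i in range(2 * n)], dtype=object),
                       np.array(["g0", "g1", "g2"], dtype=object))
        groups = np.array(["A"] * n + ["B"] * n, dtype=object)
        mt = find_markers(x, groups, min_frac=0.25, min_lnfc=0.3)
        genes_a = mt.table[mt.table.group == "A"]["gene"].tolist()
        assert "g0" not in genes_a  # 20% < 25% detection on both sides
        assert "g2" in genes_a

    def test_tied_gene_gets_p_one(self):
        data = np.ones((20, 2))
        data[:, 1] = np.r_[np.full(10, 3.0), np.full(10, 1.0)]
        x = NormMatrix(data, np.array([f"c{i}" for i in range(20)], dtype=object),
                       np.array(["tied", "real"], dtype=object))
        groups = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        mt = find_markers(x, groups, min_frac=0.0, min_lnfc=0.0)
        a = mt.table[mt.table.group == "A"].set_index("gene")
        assert a.loc["tied", "p_raw"] == 1.0
        assert a.loc["real", "p_adj"] < 0.05

    def test_small_group_rejected(self, ref_norm):
        groups = np.array(
            ["A", "A", "B"] + ["C"] * (ref_norm.n_cells - 3), dtype=object
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            find_markers(ref_norm, groups)

    def test_planted_markers_recovered(self):
        cfg = SimConfig(n_cells=400, seed=13, state_prior=(0.5, 0.5, 0.0, 0.0))
        cm, truth = generate_reference_cells(cfg)
        x = lognormalize(cm)
        mt = find_markers(x, truth.cell_state.to_numpy())
        sig = mt.significant().table
        top = sig[sig.group == "GNP_nondividing"].set_index("gene")
        planted = truth.state_signatures["GNP_nondividing"]
        recovered = [g for g in planted if g in top.index]
        assert len(recovered) >= 0.9 * len(planted)
        assert np.all(np.abs(top.loc[recovered, "ln_fc"] - 1.0) < 0.2)

    def test_no_false_markers_on_null_data(self):
        # no planted grouping: split one state's cells at random
        rng = np.random.default_rng(2)
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_cells=120, n_genes=400,
                            signature_size_per_state=10, cycling_size=10,
                            metabolic_size=10, seed=50 + seed,
                            state_prior=(1.0, 0.0, 0.0, 0.0),
                            cycling_fraction_per_state=(0, 0, 0, 0))
            cm, _ = generate_reference_cells(cfg)
            x = lognormalize(cm)
            groups = rng.permutation(
                np.array(["A", "B"] * (cfg.n_cells // 2), dtype=object)
            )
            mt = find_markers(x, groups, min_lnfc=0.0)
            hits += int((mt.table["p_adj"] < 0.05).sum())
        assert hits == 0


class TestIntersectionGrid:
    def make_tables(self, sets_a, sets_b):
        def to_table(sets):
            rows = [
                {"gene": g, "group": name, "ln_fc": 1.0, "frac_in": 1.0,
                 "frac_out": 0.0, "p_raw": 1e-6, "p_adj": 1e-5}
                for name, genes in sets.items() for g in genes
            ]
            from cbstates.markers import MarkerTable
            return MarkerTable(pd.DataFrame(rows))
        return to_table(sets_a), to_table(sets_b)

    def test_identical_sets_give_smallest_p_in_row(self):
        bg = {f"g{i}" for i in range(200)}
        shared = {f"g{i}" for i in range(20)}
        other = {f"g{i}" for i in range(100, 120)}
        ta, tb = self.make_tables({"ct": shared}, {"r1": shared, "r2": other})
        grid = intersection_grid(ta, tb, bg)
        t = grid.table.set_index("region")
        assert t.loc["r1", "p_hyper"] < t.loc["r2", "p_hyper"]
        assert t.loc["r1", "call"] == "enriched"
        assert t.loc["r2", "display"] == 0.0

    def test_empty_background_rejected(self):
        ta, tb = self.make_tables({"a": {"g1"}}, {"b": {"g1"}})
        with pytest.raises(ValueError, match="background"):
            intersection_grid(ta, tb, set())


class TestFilterStateSignature:
    def test_set_algebra(self):
        out = filter_state_signature(
            {"s": {"a", "b", "c", "d"}},
            {"s": {"b", "c", "d", "e"}},
            {"d"},
        )
        assert out == {"s": {"b", "c"}}

    def test_disjoint_inputs_error(self):
        with pytest.raises(ValueError, match="empty signature"):
            filter_state_signature({"s": {"a"}}, {"s": {"b"}}, set())

    def test_mismatched_states_error(self):
        with pytest.raises(ValueError, match="state keys"):
            filter_state_signature({"s": {"a"}}, {"t": {"a"}}, set())

    def test_planted_signatures_survive_filtering(self, spot_data):
        _, cm, spots, truth = spot_data
        x = lognormalize(cm)
        mt = find_markers(x, truth.cell_state.to_numpy(), min_lnfc=0.5)
        degs = mt.gene_sets()
        modules = {s: set(g) for s, g in truth.state_signatures.items()}
        confounders = set(truth.programs["cycling"])
        out = filter_state_signature(
            {s: degs.get(s, set()) for s in modules}, modules, confounders
        )
        for state, genes in out.items():
            planted = set(truth.state_signatures[state])
            assert len(genes & planted) >= 0.8 * len(planted)
            assert not genes & confounders


class TestCompareRegionScores:
    def make_scores(self, values, layers):
        df = pd.DataFrame({"sig": values})
        df.index = [f"s{i}" for i in range(len(df))]
        return ScoreMatrix(df), pd.Series(layers, index=df.index)

    def test_identical_distributions_p_one(self):
        vals = [1.0, 2.0, 3.0] * 2
        sm, layers = self.make_scores(vals, ["a"] * 3 + ["b"] * 3)
        out = compare_region_scores(sm, layers)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_flips_median_difference(self):
        rng = np.random.default_rng(3)
        vals = np.r_[rng.normal(0, 1, 20), rng.normal(2, 1, 20)]
        sm, layers = self.make_scores(vals, ["a"] * 20 + ["b"] * 20)
        out1 = compare_region_scores(sm, layers)
        swapped = layers.map({"a": "b", "b": "a"})
        out2 = compare_region_scores(sm, swapped)
        assert out1["median_diff"].iloc[0] == pytest.approx(
            -out2["median_diff"].iloc[0]
        )
        assert out1["p_value"].iloc[0] == pytest.approx(out2["p_value"].iloc[0])

    def test_tiny_layers_excluded(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        sm, layers = self.make_scores(vals, ["a", "a", "b", "b", "c"])
        out = compare_region_scores(sm, layers)
        assert set(out["layer_a"]) | set(out["layer_b"]) == {"a", "b"}


class TestProfileCorrelation:
    def test_identical_and_negated_profiles(self):
        genes = [f"g{i}" for i in range(10)]
        v = np.arange(10.0)
        a = pd.DataFrame([v], index=["s"], columns=genes)
        b = pd.DataFrame([v, -v], index=["r1", "r2"], columns=genes)
        out = profile_correlation(a, b, genes)
        assert out.loc["s", "r1"] == pytest.approx(1.0)
        assert out.loc["s", "r2"] == pytest.approx(-1.0)

    def test_zero_variance_profile_is_missing(self):
        genes = ["g0", "g1"]
        a = pd.DataFrame([[1.0, 1.0]], index=["s"], columns=genes)
        b = pd.DataFrame([[0.0, 2.0]], index=["r"], columns=genes)
        out = profile_correlation(a, b, genes)
        assert np.isnan(out.loc["s", "r"])

    def test_states_best_match_their_home_layer(self, spot_data):
        _, cm, spots, truth = spot_data
        xc = lognormalize(cm)
        xs = lognormalize(spots)
        genes = [g for s in truth.state_signatures.values() for g in s]
        states = truth.cell_state
        prof_c = pd.DataFrame(
            {g: 0.0 for g in genes}, index=sorted(states.unique())
        )
        dc = xc.subset_genes(genes).dense()
        for s in prof_c.index:
            prof_c.loc[s] = dc[(states == s).to_numpy()].mean(axis=0)
        layers = truth.spot_layer
        ds = xs.subset_genes(genes).dense()
        prof_r = pd.DataFrame(
            {g: 0.0 for g in genes}, index=sorted(layers.unique())
        )
        for l in prof_r.index:
            prof_r.loc[l] = ds[(layers == l).to_numpy()].mean(axis=0)
        out = profile_correlation(prof_c, prof_r, genes)
        home = {
            "GNP_dividing": "EGL_outer",
            "GNP_nondividing": "EGL_inner",
            "GN_migrating": "ML_PCL",
            "GN_mature": "IGL",
        }
        for state, layer in home.items():
            assert out.loc[state].idxmax() == layer
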