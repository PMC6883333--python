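import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socialqtl import InteractionScanModel, QtlSpec, SimConfig, simulate_family
from socialqtl.gio import INTERCROSS, TESTCROSS
from socialqtl.scan import (ComboLayout, _PairData, _perm_max_lr_complete,
                            _perm_max_lr_general, _scan_all_markers,
                            combo_index, permutation_threshold, scan_marker,
                            traditional_scan)


class TestComboLayout:
    @pytest.mark.parametrize(
        "descriptor, seg, n_combos",
        [
            ("mu", TESTCROSS, 3), ("an", TESTCROSS, 3),
            ("ag", TESTCROSS, 4), ("al", TESTCROSS, 4),
            ("mu", INTERCROSS, 6), ("ag", INTERCROSS, 9),
        ],
    )
    def test_combo_counts(self, descriptor, seg, n_combos):
        assert len(ComboLayout(descriptor, seg).combos) == n_combos

    def test_symmetric_orders_collapse(self):
        layout = ComboLayout("mu", TESTCROSS)
        assert combo_index(1, 0, layout) == combo_index(0, 1, layout)

    def test_directional_orders_distinct(self):
        layout = ComboLayout("ag", INTERCROSS)
        labels = {combo_index(a, b, layout)
                  for a, b in itertools.product((0, 1, 2), repeat=2)}
        assert len(labels) == 9

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            combo_index(2, 0, ComboLayout("mu", TESTCROSS))


class TestScanMarker:
    def test_equal_means_give_zero_lr(self):
        layout = ComboLayout("ag", TESTCROSS)
        y = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        gL = np.array([0, 0, 1, 1, 0, 1])
        gS = np.array([0, 1, 0, 1, 1, 0])
        res = scan_marker(y, gL, gS, layout)
        assert res.lr == pytest.approx(0.0, abs=1e-9)

    def test_separated_groups_capped(self):
        layout = ComboLayout("mu", TESTCROSS)
        y = np.array([1.0, 1.0, 3.0, 3.0])
        gL = np.array([0, 0, 1, 1])
        gS = np.array([0, 0, 1, 1])
        res = scan_marker(y, gL, gS, layout)
        assert res.capped
        assert res.rss1 == pytest.approx(0.0)
        assert res.lr > 50  # N*ln(RSS0/eps) scale

    def test_single_combo_degenerate(self):
        layout = ComboLayout("mu", TESTCROSS)
        y = np.array([1.0, 2.0, 3.0])
        g = np.zeros(3, dtype=int)
        res = scan_marker(y, g, g, layout)
        assert res.degenerate and res.lr == 0.0

    def test_means_match_groupby_oracle(self, qtl_family):
        """Saturated-model means equal brute-force groupby averages."""
        sim = qtl_family
        ms = sim.marker_set
        pdat = _PairData(sim.pair_tables["ag"], "ag", ms.individuals)
        for j in [0, 5, int(np.flatnonzero(ms.informative_mask())[-1])]:
            layout = ComboLayout("ag", ms.segregation[j])
            g = ms.genotypes[:, j]
            res = scan_marker(pdat.y, g[pdat.iL], g[pdat.iS], layout)
            df = pd.DataFrame({"y": pdat.y, "gL": g[pdat.iL],
                               "gS": g[pdat.iS]})
            oracle = df.groupby(["gL", "gS"])["y"].mean()
            for combo, mean in res.combo_means.items():
                if np.isfinite(mean):
                    assert mean == pytest.approx(oracle.loc[combo])

    def test_missing_pairs_dropped(self):
        layout = ComboLayout("mu", TESTCROSS)
        y = np.array([1.0, 2.0, 3.0, 9.0])
        gL = np.array([0, 1, 0, -1])
        gS = np.array([0, 1, 1, 1])
        res = scan_marker(y, gL, gS, layout, min_count=1)
        assert res.n_used == 3

    def test_affine_invariance(self, qtl_family):
        sim = qtl_family
        ms = sim.marker_set
        pdat = _PairData(sim.pair_tables["ag"], "ag", ms.individuals)
        j = 3
        layout = ComboLayout("ag", ms.segregation[j])
        g = ms.genotypes[:, j]
        base = scan_marker(pdat.y, g[pdat.iL], g[pdat.iS], layout).lr
        shifted = scan_marker(5.0 + 2.5 * pdat.y, g[pdat.iL], g[pdat.iS],
                              layout).lr
        assert shifted == pytest.approx(base, rel=1e-9)


class TestVectorisedPaths:
    @pytest.mark.parametrize(
        "family, kind",
        [("qtl_family", "ag"), ("small_null_family", "mu")],
    )
    def test_fast_scan_matches_reference(self, request, family, kind):
        sim = request.getfixturevalue(family)
        ms = sim.marker_set
        pdat = _PairData(sim.pair_tables[kind], kind, ms.individuals)
        lr_fast = _scan_all_markers(pdat, ms.genotypes, ms.segregation, kind)
        for j in range(0, ms.m, 3):
            layout = ComboLayout(kind, ms.segregation[j])
            g = ms.genotypes[:, j]
            ref = scan_marker(pdat.y, g[pdat.iL], g[pdat.iS], layout).lr
            assert lr_fast[j] == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize(
        "family, kind",
        [("qtl_family", "ag"), ("small_null_family", "mu")],
    )
    def test_permutation_paths_agree(self, request, family, kind):
        """The complete-data fast path and the general path produce the
        same genome-wide max-LR distribution for identical permutations."""
        sim = request.getfixturevalue(family)
        ms = sim.marker_set
        pdat = _PairData(sim.pair_tables[kind], kind, ms.individuals)
        perms = [np.random.default_rng(100 + i).permutation(ms.n)
                 for i in range(30)]
        fast = _perm_max_lr_complete(pdat, ms.genotypes, ms.segregation,
                                     kind, perms, 2, 16)
        general = _perm_max_lr_general(pdat, ms.genotypes, ms.segregation,
                                       kind, perms, 2, 16)
        np.testing.assert_allclose(fast, general, atol=1e-4)


class TestPermutationThreshold:
    def test_threshold_is_order_statistic(self, small_null_family):
        sim = small_null_family
        ms = sim.marker_set
        pdat = _PairData(sim.pair_tables["mu"], "mu", ms.individuals)
        n_perm = 100
        thr = permutation_threshold(sim.pair_tables["mu"], ms, "mu",
                                    alpha=0.05, n_perm=n_perm, seed=3)
        # reproduce the same permutation stream and take the 95th order
        # statistic of the genome-wide max LR directly
        rng = np.random.default_rng(3)
        perms = [rng.permutation(ms.n) for _ in range(n_perm)]
        max_lr = _perm_max_lr_complete(pdat, ms.genotypes, ms.segregation,
                                       "mu", perms, 2, 64)
        assert thr == pytest.approx(np.sort(max_lr)[94])

    def test_determinism(self, small_null_family):
        sim = small_null_family
        t1 = permutation_threshold(sim.pair_tables["mu"],
                                   sim.marker_set, "mu", n_perm=100, seed=9)
        t2 = permutation_threshold(sim.pair_tables["mu"],
                                   sim.marker_set, "mu", n_perm=100, seed=9)
        assert t1 == t2

    def test_small_n_perm_rejected(self, small_null_family):
        sim = small_null_family
        with pytest.raises(ValueError, match="at least 100"):
            permutation_threshold(sim.pair_tables["mu"], sim.marker_set,
                                  "mu", n_perm=50)
        with pytest.raises(ValueError, match="too small"):
            permutation_threshold(sim.pair_tables["mu"], sim.marker_set,
                                  "mu", alpha=0.001, n_perm=100)


class TestNullDistribution:
    def test_lr_tracks_chisquare_df(self):
        """Under no genotype effect the marker LR is approximately
        chi-square with df = combos - 1 (QQ agreement in the body)."""
        rng = np.random.default_rng(5)
        n_pairs, reps = 500, 400
        lrs = np.empty(reps)
        layout = ComboLayout("mu", TESTCROSS)
        for r in range(reps):
            y = rng.normal(0, 1, n_pairs)
            gL = rng.integers(0, 2, n_pairs)
            gS = rng.integers(0, 2, n_pairs)
            lrs[r] = scan_marker(y, gL, gS, layout).lr
        qs = np.linspace(0.1, 0.9, 9)
        observed = np.quantile(lrs, qs)
        expected = stats.chi2.ppf(qs, df=2)
        np.testing.assert_allclose(observed, expected, rtol=0.25, atol=0.3)


class TestGenomeScan:
    def test_planted_qtl_peak_recovered(self, qtl_family):
        sim = qtl_family
        res = InteractionScanModel(sim.pair_tables["ag"], sim.marker_set,
                                   "ag").fit(n_perm=200, seed=2)
        qtl = res.qtl
        assert len(qtl) >= 1
        true = sim.truth[0]
        hit = qtl[(qtl["chrom"] == true["chrom"])
                  & ((qtl["pos_cM"] - true["pos_cM"]).abs() <= 10.0)]
        assert len(hit) == 1

    def test_two_unlinked_qtl_merge_to_two_peaks(self):
        cfg = SimConfig(
            n=60, chrom_lengths_cM=(60.0, 60.0), spacing_cM=5.0,
            qtl=(
                QtlSpec(0, 30.0, "mu", {"delta_direct": 1.0,
                                        "iota_indirect": 1.0}),
                QtlSpec(1, 30.0, "mu", {"delta_direct": 1.0,
                                        "iota_indirect": 1.0}),
            ),
            h2=0.5, seed=33,
        )
        sim = simulate_family(cfg)
        res = InteractionScanModel(sim.pair_tables["mu"], sim.marker_set,
                                   "mu").fit(n_perm=200, seed=4)
        qtl = res.qtl
        assert set(qtl["chrom"]) == {0, 1}

    def test_no_informative_markers_warns(self, small_null_family):
        sim = small_null_family
        ms = sim.marker_set
        flat = ms.genotypes.copy()
        flat[:] = 0
        from socialqtl.gio import MarkerSet

        dead = MarkerSet(ms.individuals, ms.markers, flat, ms.gmap)
        model = InteractionScanModel(sim.pair_tables["mu"], dead, "mu")
        with pytest.warns(UserWarning, match="no informative"):
            res = model.fit(n_perm=100)
        assert res.significant_markers == []

    def test_summary_mentions_threshold(self, qtl_family):
        res = InteractionScanModel(qtl_family.pair_tables["ag"],
                                   qtl_family.marker_set, "ag") \
            .fit(n_perm=100, seed=0)
        text = res.summary()
        assert "threshold" in text and "QTL" in text


class TestTraditionalScan:
    def test_direct_effect_detected(self):
        cfg = SimConfig(
            n=80, chrom_lengths_cM=(60.0,), spacing_cM=5.0,
            qtl=(QtlSpec(0, 30.0, "mu", {"delta_direct": 1.5}),),
            h2=0.6, seed=8,
        )
        sim = simulate_family(cfg)
        out = traditional_scan(sim.body_mass, sim.marker_set,
                               n_perm=200, seed=1)
        assert out["significant"].any()
        peak = out.loc[out["LR"].idxmax()]
        assert abs(peak["pos_cM"] - 30.0) <= 10.0

    def test_null_mostly_clean(self, small_null_family):
        sim = small_null_family
        out = traditional_scan(sim.body_mass, sim.marker_set,
                               n_perm=200, seed=2)
        assert out["significant"].sum() == 0
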