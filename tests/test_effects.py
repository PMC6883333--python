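import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialqtl import QtlSpec, SimConfig, simulate_family
from socialqtl.effects import (INTERCROSS_EFFECTS, TESTCROSS_EFFECTS,
                               _features, partition_bodymass_at_marker,
                               partition_intercross, partition_testcross,
                               variance_components)

finite = st.floats(-50, 50, allow_nan=False)


def _forward_means(kind, mu, effects):
    """Independent forward model: enumerate combos, build means from the
    coding definitions directly (the oracle for invertibility)."""
    codes = (0, 1) if kind == "testcross" else (0, 1, 2)
    means = {}
    for gf, gp in itertools.product(codes, repeat=2):
        feats = _features(kind, gf, gp)
        means[(gf, gp)] = mu + sum(effects.get(k, 0.0) * v
                                   for k, v in feats.items())
    return means


class TestTestcrossPartition:
    def test_hand_worked_example(self):
        # ordered means for (+,+), (+,-), (-,+), (-,-) = 4, 2, 1, 1
        means = {(1, 1): 4.0, (1, 0): 2.0, (0, 1): 1.0, (0, 0): 1.0}
        ep = partition_testcross(means)
        assert ep.mu == pytest.approx(2.0)
        assert ep.effects["delta_direct"] == pytest.approx(1.0)
        assert ep.effects["iota_indirect"] == pytest.approx(0.5)
        assert ep.effects["eps_epistatic"] == pytest.approx(0.5)
        # reconstruction identity: mu + delta + iota + eps = m(+,+)
        assert ep.predict(1, 1) == pytest.approx(4.0)

    def test_constant_means_give_null_effects(self):
        means = {c: 3.0 for c in itertools.product((0, 1), repeat=2)}
        ep = partition_testcross(means)
        assert ep.mu == pytest.approx(3.0)
        assert all(v == pytest.approx(0.0) for v in ep.effects.values())

    def test_missing_combo_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            partition_testcross({(0, 0): 1.0, (0, 1): 2.0, (1, 0): 3.0})

    @given(mu=finite, delta=finite, iota=finite, eps=finite)
    @settings(max_examples=200, deadline=None)
    def test_forward_backward_identity(self, mu, delta, iota, eps):
        effects = {"delta_direct": delta, "iota_indirect": iota,
                   "eps_epistatic": eps}
        ep = partition_testcross(_forward_means("testcross", mu, effects))
        assert ep.mu == pytest.approx(mu, abs=1e-8)
        for k, v in effects.items():
            assert ep.effects[k] == pytest.approx(v, abs=1e-8)


class TestIntercrossPartition:
    def test_constant_means(self):
        means = {c: 7.0 for c in itertools.product((0, 1, 2), repeat=2)}
        ep = partition_intercross(means)
        assert ep.mu == pytest.approx(7.0)
        assert all(abs(v) < 1e-9 for v in ep.effects.values())

    def test_planted_additive_direct(self):
        means = {(gf, gp): float(gf - 1)
                 for gf, gp in itertools.product((0, 1, 2), repeat=2)}
        ep = partition_intercross(means)
        assert ep.effects["a_D"] == pytest.approx(1.0)
        others = {k: v for k, v in ep.effects.items() if k != "a_D"}
        assert all(abs(v) < 1e-9 for v in others.values())

    def test_random_means_reconstructed_exactly(self):
        rng = np.random.default_rng(4)
        means = {c: float(rng.normal())
                 for c in itertools.product((0, 1, 2), repeat=2)}
        ep = partition_intercross(means)
        for c, m in means.items():
            assert ep.predict(*c) == pytest.approx(m, abs=1e-10)

    def test_missing_cell_falls_back_with_warning(self):
        rng = np.random.default_rng(5)
        means = {c: float(rng.normal())
                 for c in itertools.product((0, 1, 2), repeat=2)}
        del means[(2, 2)]
        with pytest.warns(UserWarning, match="rank"):
            ep = partition_intercross(means)
        assert set(ep.effects) == set(INTERCROSS_EFFECTS)

    @given(values=st.lists(finite, min_size=9, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_nine_by_nine_design_invertible(self, values):
        combos = list(itertools.product((0, 1, 2), repeat=2))
        means = dict(zip(combos, values))
        ep = partition_intercross(means)
        for c, m in means.items():
            assert ep.predict(*c) == pytest.approx(m, abs=1e-6)


class TestVarianceComponents:
    def test_epistasis_only(self):
        ep = partition_testcross(_forward_means(
            "testcross", 0.0, {"eps_epistatic": 1.0}))
        shares = variance_components(ep)
        assert shares["epistatic"] == pytest.approx(1.0)
        assert shares["direct"] == pytest.approx(0.0)

    def test_symmetric_direct_indirect(self):
        ep = partition_testcross(_forward_means(
            "testcross", 0.0,
            {"delta_direct": 0.7, "iota_indirect": 0.7}))
        shares = variance_components(ep)
        assert shares["direct"] == pytest.approx(shares["indirect"])

    def test_equal_frequencies_match_squared_effects(self):
        effects = {"delta_direct": 1.0, "iota_indirect": 0.5,
                   "eps_epistatic": 0.25}
        ep = partition_testcross(_forward_means("testcross", 2.0, effects))
        shares = variance_components(ep)
        total = sum(v ** 2 for v in effects.values())
        assert shares["direct"] == pytest.approx(1.0 / total * 1.0)
        assert shares["indirect"] == pytest.approx(0.25 / total)
        assert shares["epistatic"] == pytest.approx(0.0625 / total)
        assert shares["covariance_remainder"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_flagged_undefined(self):
        ep = partition_testcross(_forward_means("testcross", 1.0, {}))
        shares = variance_components(ep)
        assert not shares["defined"]
        assert np.isnan(shares["direct"])


class TestBodymassPartition:
    @staticmethod
    def _family(effects, seed, n=80):
        cfg = SimConfig(n=n, chrom_lengths_cM=(40.0,), spacing_cM=10.0,
                        qtl=(QtlSpec(0, 20.0, "ag", effects),),
                        h2=0.4, seed=seed)
        return simulate_family(cfg)

    def test_indirect_only_recovered(self):
        sim = self._family({"iota_indirect": 1.0}, seed=3)
        j = sim.marker_set.marker_index(sim.truth[0]["marker"])
        ep = partition_bodymass_at_marker(
            sim.pair_context_mass, sim.marker_set.genotypes[:, j],
            "testcross", n_boot=0)
        assert abs(ep.effects["delta_direct"]) < 0.1
        assert ep.effects["iota_indirect"] == pytest.approx(1.0, abs=0.15)

    def test_partner_shuffle_kills_indirect_effect(self):
        """Shuffling partner identities within each focal row is a
        negative control: the indirect contrast must collapse."""
        sim = self._family({"iota_indirect": 1.0}, seed=7)
        j = sim.marker_set.marker_index(sim.truth[0]["marker"])
        rng = np.random.default_rng(0)
        shuffled = sim.pair_context_mass.copy()
        n = shuffled.shape[0]
        for i in range(n):
            others = [k for k in range(n) if k != i]
            vals = shuffled[i, others]
            shuffled[i, others] = rng.permutation(vals)
        ep = partition_bodymass_at_marker(
            shuffled, sim.marker_set.genotypes[:, j], "testcross", n_boot=0)
        assert abs(ep.effects["iota_indirect"]) < 0.1

    def test_bootstrap_deterministic(self):
        sim = self._family({"delta_direct": 0.8}, seed=9, n=40)
        j = sim.marker_set.marker_index(sim.truth[0]["marker"])
        g = sim.marker_set.genotypes[:, j]
        ep1 = partition_bodymass_at_marker(sim.pair_context_mass, g,
                                           "testcross", n_boot=50, seed=5)
        ep2 = partition_bodymass_at_marker(sim.pair_context_mass, g,
                                           "testcross", n_boot=50, seed=5)
        assert ep1.standard_errors == ep2.standard_errors
        assert all(np.isfinite(v) for v in ep1.standard_errors.values())

    def test_summary_lists_all_effects(self):
        sim = self._family({"delta_direct": 0.8}, seed=2, n=40)
        j = sim.marker_set.marker_index(sim.truth[0]["marker"])
        ep = partition_bodymass_at_marker(
            sim.pair_context_mass, sim.marker_set.genotypes[:, j],
            "testcross", n_boot=10, seed=0)
        text = ep.summary()
        for name in TESTCROSS_EFFECTS:
            assert name in text
        assert "variance shares" in text
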