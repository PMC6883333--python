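import itertools

import numpy as np
import pandas as pd
import pytest

from socialqtl import InteractionScanModel
from socialqtl.network import (SocialNetwork, build_profile_matrix,
                               classify_edges, exclusion_experiment,
                               find_hubs, infer_social_network,
                               marginal_genotypic_values)
from socialqtl.simulate import simulate_coupled_profiles


def _net_from_edges(nodes, edges):
    df = pd.DataFrame(edges, columns=["from", "to", "weight"])
    df["sign"] = np.sign(df["weight"]).astype(int) if len(df) else []
    return SocialNetwork(nodes=nodes, edges=df)


class TestClassifyEdges:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("i", "j", 2.0), ("j", "i", 1.0)], "mutualism"),
            ([("i", "j", -1.0), ("j", "i", -2.0)], "antagonism"),
            ([("i", "j", -1.0)], "aggression"),
            ([("i", "j", 1.0)], "altruism"),
            ([("i", "j", 1.0), ("j", "i", -1.0)], "aggression-with-benefit"),
        ],
    )
    def test_rules(self, edges, expected):
        net = classify_edges(_net_from_edges(["i", "j"], edges))
        assert list(net.pair_labels["label"]) == [expected]

    def test_sender_attribution(self):
        net = classify_edges(_net_from_edges(["i", "j"], [("i", "j", -1.0)]))
        assert net.pair_labels.iloc[0]["sender"] == "i"

    def test_all_sign_patterns_classified(self):
        """Every directed sign pattern on one pair maps to exactly one
        label (pure function of the two signs)."""
        for s_ab, s_ba in itertools.product([None, 1, -1], repeat=2):
            if s_ab is None and s_ba is None:
                continue
            edges = []
            if s_ab is not None:
                edges.append(("a", "b", float(s_ab)))
            if s_ba is not None:
                edges.append(("b", "a", float(s_ba)))
            net = classify_edges(_net_from_edges(["a", "b"], edges))
            assert len(net.pair_labels) == 1
            assert net.pair_labels.iloc[0]["label"] in {
                "mutualism", "antagonism", "aggression", "altruism",
                "aggression-with-benefit",
            }


class TestMarginalValues:
    def test_weighted_average_by_hand(self, qtl_family):
        sim = qtl_family
        res = InteractionScanModel(sim.pair_tables["ag"], sim.marker_set,
                                   "ag").fit(n_perm=100, seed=0)
        marker = sim.truth[0]["marker"]
        detail = res.marker_detail(marker)
        g = sim.marker_set.column(marker)
        freqs = {c: float((g == c).mean()) for c in (0, 1)}
        df = marginal_genotypic_values(res, sim.marker_set, [marker])
        expected1 = sum(freqs[b] * detail.combo_means[(1, b)]
                        for b in (0, 1))
        carrier = np.flatnonzero(g == 1)[0]
        assert df.iloc[carrier, 0] == pytest.approx(expected1)

    def test_constant_means_give_constant_column(self, small_null_family):
        sim = small_null_family
        res = InteractionScanModel(sim.pair_tables["mu"], sim.marker_set,
                                   "mu").fit(n_perm=100, seed=0)
        marker = sim.marker_set.markers[0]
        with pytest.warns(UserWarning, match="not significant"):
            df = marginal_genotypic_values(res, sim.marker_set, [marker])
        # column varies only through the combo means; spread is bounded by
        # the spread of the means themselves
        detail = res.marker_detail(marker)
        spread = np.nanmax(list(detail.combo_means.values())) - \
            np.nanmin(list(detail.combo_means.values()))
        assert df.iloc[:, 0].max() - df.iloc[:, 0].min() <= spread + 1e-12

    def test_absent_marker_rejected(self, small_null_family):
        sim = small_null_family
        res = InteractionScanModel(sim.pair_tables["mu"], sim.marker_set,
                                   "mu").fit(n_perm=100, seed=0)
        with pytest.raises(KeyError):
            marginal_genotypic_values(res, sim.marker_set, ["nope"])


class TestInference:
    def test_support_recovery_small(self):
        profiles, truth = simulate_coupled_profiles(
            n_nodes=5, q=80, snr=8.0, n_pairs=2, seed=1, target_cycles=5.0)
        net = infer_social_network(profiles, seed=1)
        found = set(zip(net.edges["from"], net.edges["to"]))
        assert found == truth

    @staticmethod
    def _independent_profiles(seed, n_nodes=10, q=160, lo=1, hi=25):
        rng = np.random.default_rng(seed)
        rows = []
        npts = 2 * (q - 1) + 2
        for _ in range(n_nodes):
            spec = np.zeros(npts // 2 + 1, complex)
            ks = np.arange(lo, hi + 1)
            spec[ks] = rng.normal(0, 1, ks.size) + 1j * rng.normal(0, 1,
                                                                   ks.size)
            s = np.fft.irfft(spec, npts)[:q]
            rows.append(s / s.std())
        return pd.DataFrame(rows, index=[f"n{i}" for i in range(n_nodes)])

    @pytest.mark.parametrize("seed", [0, 2, 3])
    def test_independent_profiles_yield_few_edges(self, seed):
        """Specificity: independent smooth profiles produce a near-empty
        network (of 90 possible directed edges)."""
        prof = self._independent_profiles(seed)
        net = infer_social_network(prof, seed=seed)
        assert net.n_edges() <= 5

    def test_identical_profiles_degenerate(self):
        prof = pd.DataFrame(np.tile(np.sin(np.linspace(0, 6, 40)), (6, 1)),
                            index=list("abcdef"))
        net = infer_social_network(prof)
        assert net.degenerate and net.n_edges() == 0

    def test_too_few_columns_rejected(self):
        prof = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 4)))
        with pytest.raises(ValueError, match="basis_order"):
            infer_social_network(prof)

    def test_permutation_equivariance(self):
        profiles, _ = simulate_coupled_profiles(
            n_nodes=8, q=80, snr=8.0, n_pairs=4, seed=3)
        net = infer_social_network(profiles, seed=0)
        perm = [5, 2, 7, 0, 1, 6, 3, 4]
        relabel = {profiles.index[i]: f"r{k}"
                   for k, i in enumerate(perm)}
        shuffled = profiles.iloc[perm].rename(index=relabel)
        net2 = infer_social_network(shuffled, seed=0)
        e1 = {(relabel[a], relabel[b]) for a, b in
              zip(net.edges["from"], net.edges["to"])}
        e2 = set(zip(net2.edges["from"], net2.edges["to"]))
        assert e1 == e2

    def test_in_degree_cap_respected(self):
        profiles, _ = simulate_coupled_profiles(
            n_nodes=12, q=120, snr=5.0, n_pairs=10, seed=4)
        net = infer_social_network(profiles, max_in_degree=2, seed=4)
        if net.n_edges():
            assert net.edges["to"].value_counts().max() <= 2


class TestHubs:
    def test_star_graph_center_is_hub(self):
        center = "c"
        leaves = [f"l{i}" for i in range(10)]
        edges = [(center, leaf, 1.0) for leaf in leaves]
        net = classify_edges(_net_from_edges([center] + leaves, edges))
        summary = find_hubs(net)
        assert summary["hubs"] == [center]

    def test_regular_graph_has_no_hubs(self):
        nodes = [f"n{i}" for i in range(6)]
        edges = [(nodes[i], nodes[(i + 1) % 6], 1.0) for i in range(6)]
        net = classify_edges(_net_from_edges(nodes, edges))
        assert find_hubs(net)["hubs"] == []

    def test_phenotype_comparison_reported(self):
        center = "c"
        leaves = [f"l{i}" for i in range(6)]
        edges = [(center, leaf, 1.0) for leaf in leaves]
        edges += [(leaf, center, -1.0) for leaf in leaves[:3]]
        net = classify_edges(_net_from_edges([center] + leaves, edges))
        phen = {center: 10.0, **{leaf: 1.0 for leaf in leaves}}
        summary = find_hubs(net, phenotypes=phen)
        assert summary["phenotype_ranksum"]["hub_median"] == 10.0
        assert "mutualism_pct" in summary and "aggression_pct" in summary

    def test_empty_network_rejected(self):
        net = _net_from_edges(["a", "b"], [])
        with pytest.raises(ValueError, match="empty"):
            find_hubs(net)


class TestExclusion:
    @pytest.fixture(scope="class")
    def scans(self, qtl_family):
        """All four descriptor scans built from the family's body masses."""
        from socialqtl import build_pair_table

        sim = qtl_family
        phen = dict(zip(sim.marker_set.individuals, sim.body_mass))
        pairs = build_pair_table(phen)
        # liberal alpha: the exclusion plumbing needs a reasonably sized
        # QTL union, not strict error control
        return sim, {
            kind: InteractionScanModel(pairs, sim.marker_set, kind)
            .fit(alpha=0.3, n_perm=100, seed=1)
            for kind in ("mu", "an", "ag", "al")
        }

    def test_exclude_none_matches_full(self, scans):
        sim, fitted = scans
        table = exclusion_experiment(fitted, sim.marker_set, exclude="none")
        assert (table["all_qtl"] == table["excluding_none"]).all()

    def test_excluding_kind_without_qtl_changes_nothing(self, scans):
        sim, fitted = scans
        # pick a kind with no significant markers of its own
        empty_kinds = [k for k, r in fitted.items()
                       if not r.significant_markers]
        if not empty_kinds:
            pytest.skip("all kinds have significant markers in fixture")
        table = exclusion_experiment(fitted, sim.marker_set,
                                     exclude=empty_kinds[0])
        assert (table["all_qtl"]
                == table[f"excluding_{empty_kinds[0]}"]).all()

    def test_profile_matrix_excludes_only_exclusive_qtl(self, scans):
        sim, fitted = scans
        full = build_profile_matrix(fitted, sim.marker_set)
        reduced = build_profile_matrix(fitted, sim.marker_set, exclude="ag")
        exclusive = {mk for mk, ks in full.qtl_kinds.items() if ks == {"ag"}}
        assert set(full.qtl) - set(reduced.qtl) == exclusive
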