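"""Direct / indirect / genome-genome epistatic decomposition of combo values.

At a QTL, the mean phenotype of a *focal* individual depends on its own
genotype (the direct effect), on its partner's genotype (the indirect
effect), and on the interaction of the two genomes (genome-genome
epistasis).  For a testcross locus (two genotypes, coded 0/1 and scored
x = ±1) the 2 x 2 table of ordered combo means m(x_f, x_p) decomposes
exactly through orthogonal contrasts:

    m = mu + delta * x_f + iota * x_p + eps * x_f * x_p

For an intercross locus (three genotypes 0/1/2) each genome contributes an
additive score x = g - 1 and a dominance indicator z = [g == 1], giving a
9-parameter saturated model

    m = mu + a_D x_f + d_D z_f + a_I x_p + d_I z_p
          + i_aa x_f x_p + i_ad x_f z_p + i_da z_f x_p + i_dd z_f z_p

whose 9 x 9 design is invertible: the partition reproduces the combo means
to machine precision.  Variance shares weight the reconstructed component
values by the observed combo frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EffectPartition",
    "partition_testcross",
    "partition_intercross",
    "variance_components",
    "partition_bodymass_at_marker",
]

TESTCROSS_EFFECTS = ["delta_direct", "iota_indirect", "eps_epistatic"]
INTERCROSS_EFFECTS = ["a_D", "d_D", "a_I", "d_I",
                      "i_aa", "i_ad", "i_da", "i_dd"]

_EFFECT_GROUP = {
    "delta_direct": "direct", "iota_indirect": "indirect",
    "eps_epistatic": "epistatic",
    "a_D": "direct", "d_D": "direct", "a_I": "indirect", "d_I": "indirect",
    "i_aa": "epistatic", "i_ad": "epistatic", "i_da": "epistatic",
    "i_dd": "epistatic",
}


@dataclass
class EffectPartition:
    """Saturated decomposition of ordered genotype-combination means."""

    kind: str  # testcross | intercross
    mu: float
    effects: dict  # effect name -> estimate (trait units)
    frequencies: dict  # ordered combo -> observed frequency
    standard_errors: dict = field(default_factory=dict)

    def predict(self, g_f: int, g_p: int) -> float:
        """Reconstructed combo mean for an ordered (focal, partner) pair."""
        feats = _features(self.kind, g_f, g_p)
        return self.mu + sum(self.effects[k] * v for k, v in feats.items())

    def component_value(self, group: str, g_f: int, g_p: int) -> float:
        """Direct / indirect / epistatic part of the reconstructed value."""
        feats = _features(self.kind, g_f, g_p)
        return sum(self.effects[k] * v for k, v in feats.items()
                   if _EFFECT_GROUP[k] == group)

    def summary(self) -> str:
        lines = [f"Effect partition ({self.kind}), mu = {self.mu:.6g}"]
        for name, val in self.effects.items():
            se = self.standard_errors.get(name)
            tail = f"  (SE {se:.4g})" if se is not None else ""
            lines.append(f"  {name:15s} [{_EFFECT_GROUP[name]:9s}] "
                         f"= {val: .6g}{tail}")
        shares = variance_components(self, self.frequencies)
        lines.append(
            "  variance shares: direct {direct:.3f}, indirect {indirect:.3f},"
            " epistatic {epistatic:.3f}".format(**shares)
        )
        return "\n".join(lines)


def _features(kind: str, g_f: int, g_p: int) -> dict:
    if kind == "testcross":
        x_f, x_p = 2 * g_f - 1, 2 * g_p - 1
        return {"delta_direct": x_f, "iota_indirect": x_p,
                "eps_epistatic": x_f * x_p}
    x_f, x_p = g_f - 1, g_p - 1
    z_f, z_p = int(g_f == 1), int(g_p == 1)
    return {"a_D": x_f, "d_D": z_f, "a_I": x_p, "d_I": z_p,
            "i_aa": x_f * x_p, "i_ad": x_f * z_p,
            "i_da": z_f * x_p, "i_dd": z_f * z_p}


def _ordered_combos(kind: str) -> list:
    codes = (0, 1) if kind == "testcross" else (0, 1, 2)
    return [(a, b) for a in codes for b in codes]


def _solve_partition(kind: str, means: dict, frequencies=None,
                     allow_missing: bool = False) -> EffectPartition:
    combos = _ordered_combos(kind)
    names = TESTCROSS_EFFECTS if kind == "testcross" else INTERCROSS_EFFECTS
    have = [c for c in combos if c in means and np.isfinite(means[c])]
    if not allow_missing and len(have) < len(combos):
        missing = [c for c in combos if c not in have]
        raise ValueError(
            f"{kind} partition requires all {len(combos)} ordered combo "
            f"means; missing {missing}"
        )
    X = np.array([[1.0] + [_features(kind, *c)[k] for k in names]
                  for c in have])
    y = np.array([means[c] for c in have])
    if len(have) == len(combos):
        beta = np.linalg.solve(X, y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            import warnings

            warnings.warn(
                f"{kind} partition rank-deficient ({rank}/{X.shape[1]}); "
                "least-squares estimates are not unique"
            )
    if frequencies is None:
        frequencies = {c: 1.0 / len(combos) for c in combos}
    total = sum(frequencies.values())
    frequencies = {c: f / total for c, f in frequencies.items()}
    return EffectPartition(
        kind=kind, mu=float(beta[0]),
        effects={k: float(b) for k, b in zip(names, beta[1:])},
        frequencies=frequencies,
    )


def partition_testcross(means: dict, frequencies=None) -> EffectPartition:
    """Exact 2 x 2 decomposition of testcross ordered combo means.

    ``means`` maps ordered genotype-code combos (g_focal, g_partner),
    g in {0, 1}, to mean phenotypes; all four are required.
    """
    return _solve_partition("testcross", means, frequencies,
                            allow_missing=False)


def partition_intercross(means: dict, frequencies=None) -> EffectPartition:
    """Exact 3 x 3 decomposition of intercross ordered combo means.

    All nine ordered combos are expected; with missing cells the partition
    falls back to least squares with a rank warning.
    """
    combos = _ordered_combos("intercross")
    have_all = all(c in means and np.isfinite(means[c]) for c in combos)
    return _solve_partition("intercross", means, frequencies,
                            allow_missing=not have_all)


def variance_components(ep: EffectPartition, frequencies=None) -> dict:
    """Variance shares of the direct / indirect / epistatic components.

    Each component's value is reconstructed per ordered combo and its
    variance taken under the combo frequencies; the three shares are
    proportions of their *sum*, with the covariance cross-term between
    components reported separately (``covariance_remainder``, as a
    fraction of total genetic variance).  All shares are flagged
    undefined (nan) when the locus carries no genetic variance.
    """
    if frequencies is None:
        frequencies = ep.frequencies
    combos = list(frequencies)
    w = np.array([frequencies[c] for c in combos], dtype=float)
    w = w / w.sum()

    def wvar(vals):
        vals = np.asarray(vals, dtype=float)
        mean = np.sum(w * vals)
        return float(np.sum(w * (vals - mean) ** 2))

    comp = {g: [ep.component_value(g, *c) for c in combos]
            for g in ("direct", "indirect", "epistatic")}
    v = {g: wvar(vals) for g, vals in comp.items()}
    total_genetic = wvar([ep.predict(*c) for c in combos])
    vsum = sum(v.values())
    if total_genetic <= 0 or vsum <= 0:
        return {"direct": np.nan, "indirect": np.nan, "epistatic": np.nan,
                "covariance_remainder": np.nan, "defined": False,
                "total_genetic_variance": total_genetic}
    out = {g: v[g] / vsum for g in v}
    out["covariance_remainder"] = (total_genetic - vsum) / total_genetic
    out["defined"] = True
    out["total_genetic_variance"] = total_genetic
    return out


# ---------------------------------------------------------------------------
# body-mass partition at a marker
# ---------------------------------------------------------------------------

def _focal_combo_means(values, genotypes, kind):
    """Ordered combo means/frequencies of the focal phenotype over pairs.

    ``values`` is either a length-n vector (one phenotype per individual,
    used as the focal value in each of its pairs) or an (n x n) matrix of
    pair-context focal phenotypes (entry (i, j) = individual i's phenotype
    when paired with j; the diagonal and any nan cells are ignored).
    Pairs with a missing genotype at this marker are dropped.
    """
    g = np.asarray(genotypes)
    values = np.asarray(values, dtype=float)
    n = g.shape[0]
    k = 2 if kind == "testcross" else 3
    E = np.zeros((n, k))
    ok = g >= 0
    E[np.flatnonzero(ok), g[ok]] = 1.0
    if values.ndim == 1:
        V = np.broadcast_to(values[:, None], (n, n)).copy()
        np.fill_diagonal(V, np.nan)
    else:
        V = values.copy()
        np.fill_diagonal(V, np.nan)
    W = np.isfinite(V).astype(float)
    sums = E.T @ np.where(np.isfinite(V), V, 0.0) @ E
    counts = E.T @ W @ E
    total = counts.sum()
    means, freqs = {}, {}
    for a in range(k):
        for b in range(k):
            c = (a, b)
            means[c] = sums[a, b] / counts[a, b] if counts[a, b] else np.nan
            freqs[c] = counts[a, b] / total if total else 0.0
    return means, freqs


def partition_bodymass_at_marker(
    body_mass,
    genotypes: np.ndarray,
    segregation: str,
    n_boot: int = 200,
    seed=0,
) -> EffectPartition:
    """Partition the focal phenotype over (own genotype, partner genotype).

    ``body_mass`` is either one value per individual (used as the focal
    value in each of its pairs; indirect contrasts then rest entirely on
    pair-context variation, which a single shared phenotype cannot
    provide) or an (n x n) matrix of pair-context focal phenotypes (entry
    (i, j) = i's phenotype when paired with j).  Ordered combo means over
    all pairs feed the matching saturated partition; standard errors come
    from a nonparametric bootstrap over *individuals* (not pairs),
    respecting the dependence created by shared pair membership.
    Deterministic given ``seed``.
    """
    if segregation not in ("testcross", "intercross"):
        raise ValueError(f"cannot partition a {segregation!r} marker")
    y = np.asarray(body_mass, dtype=float)
    g = np.asarray(genotypes)
    if y.shape[0] != g.shape[0]:
        raise ValueError("body mass and genotype lengths differ")
    means, freqs = _focal_combo_means(y, g, segregation)
    part = (partition_testcross if segregation == "testcross"
            else partition_intercross)
    ep = part(means, freqs)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        names = list(ep.effects)
        draws = {k: [] for k in names + ["mu"]}
        n = g.shape[0]
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            yb = y[take] if y.ndim == 1 else y[np.ix_(take, take)]
            try:
                bm, bf = _focal_combo_means(yb, g[take], segregation)
                bep = part(bm, bf)
            except (ValueError, np.linalg.LinAlgError):
                continue  # resample lost a genotype class
            draws["mu"].append(bep.mu)
            for k in names:
                draws[k].append(bep.effects[k])
        ep.standard_errors = {
            k: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
            for k, v in draws.items()
        }
    return ep
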