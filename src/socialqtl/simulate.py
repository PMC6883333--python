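"""Synthetic full-sib families with planted interaction QTL.

The generator emulates the mapping design the scan is built for: one F1
full-sib family genotyped at evenly spaced markers on a known linkage map.
Gametes are simulated as Markov walks along each chromosome with
recombination fractions from the Haldane map function
``r = (1 - e^(-2d/100)) / 2`` (d in cM, no crossover interference).
Testcross markers are informative in one parent (offspring codes 0/1,
segregating 1:1); intercross markers in both (codes 0/1/2, 1:2:1).

Planted QTL carry effect vectors in the saturated parameterization of
:mod:`socialqtl.effects` (direct / indirect / genome-genome epistatic;
additive + dominance for intercross loci).  Pair phenotypes are the summed
effect-model means over planted QTL for the pair's ordered genotype
combination, plus Gaussian residual noise scaled so that the genetic share
of the pair-phenotype variance equals the requested heritability.  An
individual's body mass is its mean focal pair value plus individual noise
at the same heritability — so indirect effects, which average out over
partners, are invisible to a traditional own-genotype scan by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import PairTable
from .effects import EffectPartition, TESTCROSS_EFFECTS, INTERCROSS_EFFECTS
from .gio import INTERCROSS, TESTCROSS, MarkerSet
from .scan import (InteractionScanModel, _PairData, _permutation_max_lr,
                   _scan_all_markers, traditional_scan)

__all__ = [
    "QtlSpec",
    "SimConfig",
    "SimResult",
    "simulate_fullsib_genotypes",
    "simulate_pair_phenotypes",
    "simulate_family",
    "power_fpr_experiment",
]


@dataclass(frozen=True)
class QtlSpec:
    """One planted QTL: map location, descriptor kind, effect vector."""

    chrom: int  # chromosome index (0-based)
    pos_cM: float
    kind: str  # mu | an | ag | al
    effects: dict  # effect name -> value (effect-partition parameterization)
    mu: float = 0.0

    @property
    def segregation(self) -> str:
        names = set(self.effects)
        if names <= set(TESTCROSS_EFFECTS):
            return TESTCROSS
        if names <= set(INTERCROSS_EFFECTS):
            return INTERCROSS
        raise ValueError(f"unrecognised effect names: {sorted(names)}")

    def partition(self) -> EffectPartition:
        names = (TESTCROSS_EFFECTS if self.segregation == TESTCROSS
                 else INTERCROSS_EFFECTS)
        effects = {k: float(self.effects.get(k, 0.0)) for k in names}
        return EffectPartition(kind=self.segregation, mu=self.mu,
                               effects=effects, frequencies={})


@dataclass
class SimConfig:
    """Study conditions for one simulated mapping family.

    Defaults are the package's standard scenario: a family of 70 sibs on
    5 chromosomes of 100 cM at 1 cM marker spacing, an even mix of
    testcross and intercross markers, heritability 0.4.
    """

    n: int = 70
    chrom_lengths_cM: tuple = (100.0,) * 5
    spacing_cM: float = 1.0
    testcross_fraction: float = 0.5
    qtl: tuple = ()
    h2: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("family size must be at least 4")
        if not 0 < self.h2 < 1:
            raise ValueError("heritability must lie in (0, 1)")
        if self.spacing_cM <= 0:
            raise ValueError("marker spacing must be positive")
        for q in self.qtl:
            if not 0 <= q.chrom < len(self.chrom_lengths_cM):
                raise ValueError(f"QTL chromosome {q.chrom} out of range")
            if not 0 <= q.pos_cM <= self.chrom_lengths_cM[q.chrom]:
                raise ValueError(f"QTL position {q.pos_cM} outside chromosome")

    @property
    def kinds(self) -> list:
        ks = sorted({q.kind for q in self.qtl})
        return ks if ks else ["mu"]


@dataclass
class SimResult:
    """A simulated family with its ground truth."""

    marker_set: MarkerSet
    body_mass: np.ndarray
    pair_tables: dict  # descriptor kind -> PairTable
    truth: list  # per QTL: dict(marker, chrom, pos_cM, kind, effects)
    realized_h2: dict  # descriptor kind -> realized genetic variance share
    pair_context_mass: np.ndarray = None  # (n, n) focal-by-partner phenotype


def haldane_r(d_cM) -> np.ndarray:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _simulate_gametes(rng, n, positions) -> np.ndarray:
    """Allele-origin (0/1) Markov walk along one chromosome for n gametes."""
    m = positions.size
    alleles = np.empty((n, m), dtype=np.int8)
    alleles[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        r = haldane_r(np.diff(positions))
        flips = rng.random((n, m - 1)) < r
        alleles[:, 1:] = flips
        np.bitwise_xor.accumulate(alleles, axis=1, out=alleles)
    return alleles


def simulate_fullsib_genotypes(cfg: SimConfig, rng=None) -> MarkerSet:
    """Simulate the genotype matrix + map of one full-sib family.

    Marker segregation types are drawn from ``cfg.testcross_fraction``;
    markers hosting a planted QTL are forced to that QTL's type.  For a
    testcross marker the informative parent is drawn at random and the
    offspring code is that parent's transmitted allele; intercross codes
    are the summed transmitted alleles of both parents.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    markers, chroms, poss, segs = [], [], [], []
    qtl_at = {}
    for c, length in enumerate(cfg.chrom_lengths_cM):
        positions = np.arange(0.0, length + 1e-9, cfg.spacing_cM)
        for p in positions:
            markers.append(f"m{c}_{p:g}")
            chroms.append(c)
            poss.append(float(p))
            segs.append(TESTCROSS if rng.random() < cfg.testcross_fraction
                        else INTERCROSS)
    chroms = np.array(chroms)
    poss = np.array(poss)
    segs = np.array(segs, dtype=object)

    for q in cfg.qtl:
        on_chrom = np.flatnonzero(chroms == q.chrom)
        j = on_chrom[np.argmin(np.abs(poss[on_chrom] - q.pos_cM))]
        if abs(poss[j] - q.pos_cM) > 1e-9:
            raise ValueError(
                f"QTL position {q.pos_cM} cM does not coincide with a "
                f"marker (nearest {poss[j]} cM)"
            )
        segs[j] = q.segregation
        qtl_at[(q.chrom, q.pos_cM)] = markers[j]

    geno = np.empty((cfg.n, len(markers)), dtype=np.int8)
    informative_parent = rng.integers(0, 2, size=len(markers))
    for c in range(len(cfg.chrom_lengths_cM)):
        cols = np.flatnonzero(chroms == c)
        g1 = _simulate_gametes(rng, cfg.n, poss[cols])
        g2 = _simulate_gametes(rng, cfg.n, poss[cols])
        both = g1 + g2
        for local, j in enumerate(cols):
            if segs[j] == TESTCROSS:
                geno[:, j] = (g1 if informative_parent[j] == 0
                              else g2)[:, local]
            else:
                geno[:, j] = both[:, local]

    gmap = pd.DataFrame({"marker": markers, "chrom": chroms, "pos_cM": poss})
    return MarkerSet(
        individuals=[f"ind{i:03d}" for i in range(cfg.n)],
        markers=markers, genotypes=geno, gmap=gmap, segregation=segs,
    )


def _scale_noise(genetic: np.ndarray, h2: float, rng) -> np.ndarray:
    """Add Gaussian noise so genetic/total variance equals h2 (empirically)."""
    var_g = float(np.var(genetic))
    if var_g <= 0:
        raise ValueError(
            "requested heritability but the planted QTL generate zero "
            "genetic variance"
        )
    sigma = np.sqrt(var_g * (1.0 - h2) / h2)
    return genetic + rng.normal(0.0, sigma, size=genetic.shape)


def simulate_pair_phenotypes(ms: MarkerSet, cfg: SimConfig,
                             rng=None) -> SimResult:
    """Pair descriptor phenotypes and body masses from planted QTL.

    Returns one pair table per descriptor kind in the QTL spec (pure-noise
    tables in null mode), with pairs keyed larger-first by body mass.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = ms.n
    marker_pos = {(int(ms.gmap["chrom"][j]), float(ms.gmap["pos_cM"][j])): j
                  for j in range(ms.m)}

    # genetic value of ordered pair (focal i, partner j) per descriptor kind
    genetic = {k: np.zeros((n, n)) for k in cfg.kinds}
    truth = []
    for q in cfg.qtl:
        j = marker_pos[(q.chrom, q.pos_cM)]
        ep = q.partition()
        g = ms.genotypes[:, j]
        codes = (0, 1) if q.segregation == TESTCROSS else (0, 1, 2)
        lut = np.array([[ep.predict(a, b) for b in codes] for a in codes])
        genetic[q.kind] += lut[np.ix_(g, g)]
        truth.append({"marker": ms.markers[j], "chrom": q.chrom,
                      "pos_cM": q.pos_cM, "kind": q.kind,
                      "segregation": q.segregation, "effects": dict(q.effects)})

    # pair-context focal mass: total genetic value of the ordered pair plus
    # noise at h2; per-individual body mass is its mean over partners
    total_genetic = sum(genetic.values())
    off_diag = ~np.eye(n, dtype=bool)
    if cfg.qtl and np.var(total_genetic[off_diag]) > 0:
        var_g = float(np.var(total_genetic[off_diag]))
        sigma = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
    else:
        sigma = 1.0
    context = total_genetic + rng.normal(0.0, sigma, size=(n, n))
    np.fill_diagonal(context, np.nan)
    # body mass: the individual's mean genetic value over partners plus a
    # residual on the same trait scale as the pair-context noise (so a
    # purely indirect architecture leaves body mass without a detectable
    # own-genotype signal, while a direct architecture keeps h2)
    body_gen = np.nansum(np.where(off_diag, total_genetic, 0.0),
                         axis=1) / (n - 1)
    body = body_gen + rng.normal(0.0, sigma, size=n)
    shift = -body.min() + 1.0  # keep trait positive
    body = body + shift
    context = context + shift

    iu, ju = np.triu_indices(n, k=1)
    larger_first = body[iu] >= body[ju]
    iL = np.where(larger_first, iu, ju)
    iS = np.where(larger_first, ju, iu)

    pair_tables, realized = {}, {}
    ids = np.array(ms.individuals, dtype=object)
    for kind in cfg.kinds:
        gvals = genetic[kind][iL, iS]  # focal = larger member
        if np.var(gvals) > 0:
            values = _scale_noise(gvals, cfg.h2, rng)
            realized[kind] = float(np.var(gvals) / np.var(values))
        else:
            values = rng.normal(0.0, 1.0, size=gvals.size)
            realized[kind] = 0.0
        tbl = pd.DataFrame({
            "id_L": ids[iL], "id_S": ids[iS],
            "w_L": body[iL], "w_S": body[iS],
            "z_mu": np.nan, "z_an": np.nan, "z_ag": np.nan, "z_al": np.nan,
            "defined_mu_an": True,
        })
        tbl["z_" + kind] = values
        pair_tables[kind] = PairTable(tbl)

    return SimResult(marker_set=ms, body_mass=body, pair_tables=pair_tables,
                     truth=truth, realized_h2=realized,
                     pair_context_mass=context)


def simulate_family(cfg: SimConfig) -> SimResult:
    """Genotypes + phenotypes for one family; byte-identical given seed."""
    rng = np.random.default_rng(cfg.seed)
    ms = simulate_fullsib_genotypes(cfg, rng)
    return simulate_pair_phenotypes(ms, cfg, rng)


def simulate_coupled_profiles(
    n_nodes: int = 20,
    q: int = 240,
    snr: float = 5.0,
    n_pairs: int = 10,
    seed: int = 0,
    target_cycles: float = 12.0,
):
    """Synthetic genotypic-profile matrix with planted sparse couplings.

    A sparse antisymmetric coupling matrix over ``n_pairs`` node pairs plus
    a uniform decay drives a coupled-oscillator system dG/dt = A G; its
    trajectory sampled at ``q`` points along the axis gives every node an
    oscillatory profile (antisymmetric coupling keeps all modes alive and
    their frequencies spread, so profiles stay mutually distinguishable).
    Each node's derivative is then *exactly* the planted sparse linear
    combination of its neighbours' profiles — the ground truth the network
    inference is scored against.  Gaussian observation noise is added at
    ``snr`` (profile SD over noise SD).

    Returns ``(profiles, truth)``: a DataFrame (nodes x axis points) and
    the set of true directed edges (j, i) for node names ``n<j> -> n<i>``.
    """
    from scipy.linalg import eigvals, expm

    rng = np.random.default_rng(seed)
    A = np.zeros((n_nodes, n_nodes))
    truth = set()
    pairs = set()
    while len(pairs) < n_pairs:
        i, j = rng.choice(n_nodes, 2, replace=False)
        pairs.add((min(i, j), max(i, j)))
    for i, j in sorted(pairs):
        w = rng.choice([-1, 1]) * rng.uniform(0.7, 1.0)
        A[i, j] = w
        A[j, i] = -w
        truth.add((j, i))
        truth.add((i, j))
    T = 2.0
    wmax = float(np.abs(eigvals(A).imag).max()) or 1.0
    A *= (2.0 * np.pi * target_cycles / T) / wmax
    A -= 0.25 * np.eye(n_nodes)
    t = np.linspace(0.0, T, q)
    P = expm(A * (t[1] - t[0]))
    G = np.empty((n_nodes, q))
    G[:, 0] = rng.normal(0, 1, n_nodes)
    for k in range(1, q):
        G[:, k] = P @ G[:, k - 1]
    sd = G.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    G = G + rng.normal(0, 1, G.shape) * (sd / snr)
    names = [f"n{i}" for i in range(n_nodes)]
    profiles = pd.DataFrame(G, index=names)
    return profiles, {(f"n{j}", f"n{i}") for (j, i) in truth}


# ---------------------------------------------------------------------------
# power / false-positive-rate harness
# ---------------------------------------------------------------------------

def _fast_scan_significant(sim: SimResult, kind: str, alpha: float,
                           n_perm: int, seed, min_count: int = 2):
    """(LR vector, threshold) via the vectorised scan + permutation path."""
    ms = sim.marker_set
    pdat = _PairData(sim.pair_tables[kind], kind, ms.individuals)
    informative = ms.informative_mask()
    lr = np.full(ms.m, np.nan)
    lr[informative] = _scan_all_markers(
        pdat, ms.genotypes[:, informative], ms.segregation[informative],
        kind, min_count,
    )
    max_lr = _permutation_max_lr(
        pdat, ms.genotypes[:, informative], ms.segregation[informative],
        kind, n_perm, seed, min_count,
    )
    k = int(np.ceil((1.0 - alpha) * n_perm))
    threshold = float(np.sort(max_lr)[k - 1])
    return lr, threshold


def _hits_near_truth(ms: MarkerSet, sig_idx, truth, window_cM: float) -> bool:
    chroms = ms.gmap["chrom"].to_numpy()
    poss = ms.gmap["pos_cM"].to_numpy()
    for q in truth:
        near = (chroms[sig_idx] == q["chrom"]) & (
            np.abs(poss[sig_idx] - q["pos_cM"]) <= window_cM)
        if near.any():
            return True
    return False


def power_fpr_experiment(
    configs: list,
    n_reps: int = 100,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
    window_cM: float = 10.0,
    traditional_arm: bool = True,
) -> pd.DataFrame:
    """Monte Carlo power / family-wise false-positive-rate table.

    For each configuration, ``n_reps`` families are simulated and scanned
    at the ``alpha`` genome-wide permutation threshold.  Under a null
    configuration (no QTL) the reported rate is the family-wise
    false-positive rate: the fraction of replicates declaring any marker.
    Under planted QTL it is power: the fraction of replicates with a
    significant marker within ``window_cM`` of a true QTL.  The
    ``traditional`` arm runs the one-way own-genotype ANOVA scan on body
    mass over the same data.
    """
    rows = []
    root = np.random.default_rng(seed)
    for ci, cfg in enumerate(configs):
        rep_seeds = root.integers(0, 2 ** 31 - 1, size=(n_reps, 3))
        hits = {"pair": 0, "traditional": 0}
        any_sig = {"pair": 0, "traditional": 0}
        for rep in range(n_reps):
            rep_cfg = SimConfig(
                n=cfg.n, chrom_lengths_cM=cfg.chrom_lengths_cM,
                spacing_cM=cfg.spacing_cM,
                testcross_fraction=cfg.testcross_fraction,
                qtl=cfg.qtl, h2=cfg.h2, seed=int(rep_seeds[rep, 0]),
            )
            sim = simulate_family(rep_cfg)
            kind = rep_cfg.kinds[0]
            lr, thr = _fast_scan_significant(
                sim, kind, alpha, n_perm, int(rep_seeds[rep, 1]))
            sig = np.flatnonzero(np.nan_to_num(lr) > thr)
            if sig.size:
                any_sig["pair"] += 1
                if sim.truth and _hits_near_truth(sim.marker_set, sig,
                                                  sim.truth, window_cM):
                    hits["pair"] += 1
            if traditional_arm:
                tr = traditional_scan(sim.body_mass, sim.marker_set,
                                      alpha=alpha, n_perm=n_perm,
                                      seed=int(rep_seeds[rep, 2]))
                tsig = np.flatnonzero(tr["significant"].to_numpy())
                if tsig.size:
                    any_sig["traditional"] += 1
                    if sim.truth and _hits_near_truth(
                            sim.marker_set, tsig, sim.truth, window_cM):
                        hits["traditional"] += 1
        arms = ["pair"] + (["traditional"] if traditional_arm else [])
        for arm in arms:
            rows.append({
                "condition": ci, "model": arm, "n": cfg.n, "h2": cfg.h2,
                "n_qtl": len(cfg.qtl), "n_reps": n_reps, "alpha": alpha,
                "power": (hits[arm] / n_reps if cfg.qtl else np.nan),
                "fwer": (any_sig[arm] / n_reps if not cfg.qtl else np.nan),
                "any_significant_rate": any_sig[arm] / n_reps,
            })
    return pd.DataFrame(rows)
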