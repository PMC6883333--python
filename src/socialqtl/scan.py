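"""Genome-wide scan for interaction QTL from pairwise descriptor phenotypes.

Each unordered pair of individuals in a co-cultured full-sib family carries
a descriptor phenotype (mutualism, antagonism, aggression or altruism, see
:mod:`socialqtl.descriptors`).  At a marker, a pair also carries a
*genotype combination* — the pair of genotype codes of its two members.
Symmetric descriptors (mutualism, antagonism) do not distinguish which
member carries which genotype; directional descriptors (aggression,
altruism) key the combination as (genotype of the larger member, genotype
of the smaller member).  The number of combinations is therefore

======================  =========  ===========
segregation             symmetric  directional
======================  =========  ===========
testcross  (codes 0/1)      3           4
intercross (codes 0-2)      6           9
======================  =========  ===========

The scan statistic at a marker compares a full model with one normal mean
per occupied combination (common variance) against a single-mean null:

    LR = N * ln(RSS0 / RSS1)

with N the usable pairs at the marker.  Pairs share individuals and are
therefore dependent; the working likelihood ignores this, and all error
control is instead by an *individual-level* permutation: individual
identities are permuted against the genotype matrix (each individual's
whole-genome genotype vector stays intact), the pair combinations are
rebuilt against the fixed pair phenotypes, and the genome-wide maximum LR
per permutation yields the empirical genome-wide threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import PairTable
from .gio import INTERCROSS, TESTCROSS, MarkerSet

__all__ = [
    "ComboLayout",
    "combo_index",
    "scan_marker",
    "InteractionScanModel",
    "InteractionScanResults",
    "permutation_threshold",
    "traditional_scan",
]

SYMMETRIC_DESCRIPTORS = {"mu", "an"}
DIRECTIONAL_DESCRIPTORS = {"ag", "al"}

#: relative floor for a vanishing full-model RSS (times the variance scale)
RSS_EPS_FACTOR = 1e-12


@dataclass(frozen=True)
class ComboLayout:
    """Genotype-combination layout for one descriptor x segregation type."""

    descriptor: str  # mu | an | ag | al
    segregation: str  # testcross | intercross

    def __post_init__(self):
        if self.descriptor not in SYMMETRIC_DESCRIPTORS | DIRECTIONAL_DESCRIPTORS:
            raise ValueError(f"unknown descriptor {self.descriptor!r}")
        if self.segregation not in (TESTCROSS, INTERCROSS):
            raise ValueError(f"unknown segregation type {self.segregation!r}")

    @property
    def symmetric(self) -> bool:
        return self.descriptor in SYMMETRIC_DESCRIPTORS

    @property
    def classes(self) -> tuple:
        return (0, 1) if self.segregation == TESTCROSS else (0, 1, 2)

    @property
    def combos(self) -> list:
        """Combo labels: (g_L, g_S) tuples, unordered-canonical if symmetric."""
        cls = self.classes
        if self.symmetric:
            return [(a, b) for a in cls for b in cls if a <= b]
        return [(a, b) for a in cls for b in cls]


def combo_index(g_L: int, g_S: int, layout: ComboLayout):
    """Map a pair's genotype codes to its combo label under a layout."""
    cls = layout.classes
    if g_L not in cls or g_S not in cls:
        raise ValueError(
            f"genotype codes ({g_L},{g_S}) invalid for {layout.segregation}"
        )
    if layout.symmetric:
        return (min(g_L, g_S), max(g_L, g_S))
    return (g_L, g_S)


# ---------------------------------------------------------------------------
# single-marker reference statistic
# ---------------------------------------------------------------------------

@dataclass
class MarkerScan:
    """Combo means, counts and the LR statistic at one marker."""

    combo_means: dict
    combo_counts: dict
    n_used: int
    rss0: float
    rss1: float
    lr: float
    residual_variance: float
    degenerate: bool = False
    capped: bool = False


def _lr_from_groups(sums, sumsqs, counts):
    """LR and bookkeeping from per-combo sufficient statistics."""
    n = counts.sum()
    if n == 0 or (counts > 0).sum() < 2:
        s_tot = sums.sum()
        ss_tot = sumsqs.sum()
        rss0 = ss_tot - (s_tot ** 2 / n if n else 0.0)
        return 0.0, max(rss0, 0.0), max(rss0, 0.0), True, False
    s_tot, ss_tot = sums.sum(), sumsqs.sum()
    rss0 = max(ss_tot - s_tot ** 2 / n, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = max(float(ss_tot - np.sum(
            np.where(counts > 0, sums ** 2 / np.where(counts > 0, counts, 1), 0.0)
        )), 0.0)
    eps = RSS_EPS_FACTOR * max(rss0 / n, np.finfo(float).tiny)
    capped = rss1 <= eps
    lr = n * np.log(rss0 / max(rss1, eps)) if rss0 > 0 else 0.0
    return max(float(lr), 0.0), rss0, rss1, False, capped


def scan_marker(
    pair_values: np.ndarray,
    g_L: np.ndarray,
    g_S: np.ndarray,
    layout: ComboLayout,
    min_count: int = 2,
) -> MarkerScan:
    """Combo means and the LR statistic at one marker (reference path).

    ``pair_values`` holds one descriptor value per pair; ``g_L``/``g_S``
    the genotype codes of the pair's larger/smaller member (``-1`` =
    missing; those pairs are dropped for this marker only).  Combos
    occupied by fewer than ``min_count`` pairs are dropped with df
    adjustment so that the statistic matches the vectorised permutation
    path exactly.
    """
    y = np.asarray(pair_values, dtype=float)
    g_L = np.asarray(g_L)
    g_S = np.asarray(g_S)
    usable = (g_L >= 0) & (g_S >= 0)
    combos = layout.combos
    sums = np.zeros(len(combos))
    sumsqs = np.zeros(len(combos))
    counts = np.zeros(len(combos), dtype=int)
    pos = {c: k for k, c in enumerate(combos)}
    for yi, a, b in zip(y[usable], g_L[usable], g_S[usable]):
        k = pos[combo_index(int(a), int(b), layout)]
        sums[k] += yi
        sumsqs[k] += yi * yi
        counts[k] += 1
    keep = counts >= min_count
    lr, rss0, rss1, degenerate, capped = _lr_from_groups(
        sums[keep], sumsqs[keep], counts[keep]
    )
    n_used = int(counts[keep].sum())
    means = {c: (sums[k] / counts[k] if counts[k] else np.nan)
             for c, k in pos.items()}
    resid_var = rss1 / n_used if n_used else np.nan
    return MarkerScan(
        combo_means=means,
        combo_counts={c: int(counts[k]) for c, k in pos.items()},
        n_used=n_used, rss0=rss0, rss1=rss1, lr=lr,
        residual_variance=resid_var, degenerate=degenerate, capped=capped,
    )


# ---------------------------------------------------------------------------
# vectorised engine: all markers (and permutation batches) at once
# ---------------------------------------------------------------------------

class _PairData:
    """Pair phenotypes mapped onto individual indices of a MarkerSet."""

    def __init__(self, pair_table: PairTable, descriptor: str,
                 individuals: list):
        idx = {ind: i for i, ind in enumerate(individuals)}
        rows = pair_table.values_for(descriptor)
        missing = set(rows["id_L"]) | set(rows["id_S"])
        missing -= set(idx)
        if missing:
            raise ValueError(
                f"pair table references individuals absent from the marker "
                f"set: {sorted(missing)[:5]}"
            )
        self.iL = rows["id_L"].map(idx).to_numpy(dtype=np.intp)
        self.iS = rows["id_S"].map(idx).to_numpy(dtype=np.intp)
        self.y = rows["value"].to_numpy(dtype=float)
        self.n = len(individuals)
        self.n_pairs = len(self.y)

    def value_matrices(self, symmetric: bool):
        """Dense (n x n) value/value²/mask matrices indexed (larger, smaller).

        Symmetric descriptors mirror the value into both triangles.
        """
        n = self.n
        Y = np.zeros((n, n))
        M = np.zeros((n, n))
        Y[self.iL, self.iS] = self.y
        M[self.iL, self.iS] = 1.0
        if symmetric:
            Y[self.iS, self.iL] = self.y
            M[self.iS, self.iL] = 1.0
        return Y, Y * Y, M


def _combo_stats_block(E: dict, Y, Y2, M, layout: ComboLayout):
    """Per-combo (sum, sumsq, count) arrays over a block of marker columns.

    ``E[a]`` is the (n x m) 0/1 indicator of genotype class ``a``.  For an
    ordered class pair the quadratic form
    ``colsum(E_a * (Y @ E_b))`` sums the pair values over pairs whose larger
    member carries ``a`` and smaller carries ``b``; the symmetric same-class
    case counts each pair twice and is halved.
    """
    YE = {b: Y @ Eb for b, Eb in E.items()}
    Y2E = {b: Y2 @ Eb for b, Eb in E.items()}
    ME = {b: M @ Eb for b, Eb in E.items()}
    sums, sumsqs, counts = [], [], []
    for (a, b) in layout.combos:
        s = np.einsum("im,im->m", E[a], YE[b])
        ss = np.einsum("im,im->m", E[a], Y2E[b])
        c = np.einsum("im,im->m", E[a], ME[b])
        if layout.symmetric and a == b:
            s, ss, c = s / 2.0, ss / 2.0, c / 2.0
        sums.append(s)
        sumsqs.append(ss)
        counts.append(c)
    return np.array(sums), np.array(sumsqs), np.array(counts)


def _lr_vector(sums, sumsqs, counts, min_count: int):
    """Vectorised LR over markers from (k x m) combo sufficient stats."""
    keep = counts >= min_count
    c = np.where(keep, counts, 0.0)
    s = np.where(keep, sums, 0.0)
    ss = np.where(keep, sumsqs, 0.0)
    n = c.sum(axis=0)
    s_tot = s.sum(axis=0)
    ss_tot = ss.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = ss_tot - np.where(n > 0, s_tot ** 2 / np.where(n > 0, n, 1), 0.0)
        rss1 = ss_tot - np.where(c > 0, s ** 2 / np.where(c > 0, c, 1), 0.0).sum(axis=0)
    rss0 = np.maximum(rss0, 0.0)
    rss1 = np.maximum(rss1, 0.0)
    eps = RSS_EPS_FACTOR * np.maximum(
        np.where(n > 0, rss0 / np.where(n > 0, n, 1), 0.0), np.finfo(float).tiny
    )
    occupied = (c > 0).sum(axis=0)
    lr = np.where(
        (occupied >= 2) & (rss0 > 0),
        n * np.log(np.maximum(rss0, np.finfo(float).tiny)
                   / np.maximum(rss1, eps)),
        0.0,
    )
    return np.maximum(lr, 0.0), rss0, rss1, n


def _scan_all_markers(pd_data: _PairData, genotypes: np.ndarray,
                      segregation: np.ndarray, descriptor: str,
                      min_count: int = 2) -> np.ndarray:
    """LR for every marker column, grouped by segregation type."""
    m = genotypes.shape[1]
    lr = np.zeros(m)
    for seg in (TESTCROSS, INTERCROSS):
        cols = np.flatnonzero(segregation == seg)
        if cols.size == 0:
            continue
        layout = ComboLayout(descriptor, seg)
        Y, Y2, M = pd_data.value_matrices(layout.symmetric)
        G = genotypes[:, cols]
        E = {a: (G == a).astype(float) for a in layout.classes}
        sums, sumsqs, counts = _combo_stats_block(E, Y, Y2, M, layout)
        lr[cols] = _lr_vector(sums, sumsqs, counts, min_count)[0]
    return lr


def _perm_max_lr_complete(
    pd_data: _PairData, genotypes: np.ndarray, segregation: np.ndarray,
    descriptor: str, perms: list, min_count: int, chunk: int,
) -> np.ndarray:
    """Permutation max-LR fast path for fully observed genotype matrices.

    With no missing genotypes every pair is usable at every marker, so the
    null-model RSS and the total sum of squares are permutation- and
    marker-invariant; only the per-combo sums and counts move.  The last
    genotype class is derived by complement and the matmuls run in float32.
    The rare marker x permutation cells where a combo falls below
    ``min_count`` (and would be dropped with df adjustment) are recomputed
    through the reference path.
    """
    n_perm = len(perms)
    max_lr = np.full(n_perm, -np.inf)
    y = pd_data.y
    n_pairs = pd_data.n_pairs
    ss_tot = float(y @ y)
    s_tot = float(y.sum())
    rss0 = max(ss_tot - s_tot ** 2 / n_pairs, 0.0)
    eps = RSS_EPS_FACTOR * max(rss0 / n_pairs, np.finfo(float).tiny)

    for seg in (TESTCROSS, INTERCROSS):
        cols = np.flatnonzero(segregation == seg)
        if cols.size == 0:
            continue
        layout = ComboLayout(descriptor, seg)
        Y, _, M = pd_data.value_matrices(layout.symmetric)
        Y32 = Y.astype(np.float32)
        M32 = M.astype(np.float32)
        rowsum_Y = Y32.sum(axis=1)
        rowsum_M = M32.sum(axis=1)
        G = genotypes[:, cols]
        m = cols.size
        classes = layout.classes
        E0 = {a: (G == a).astype(np.float32) for a in classes[:-1]}
        E0_last = (G == classes[-1]).astype(np.float32)
        for start in range(0, n_perm, chunk):
            batch = perms[start:start + chunk]
            p = len(batch)
            E = {a: np.concatenate([E0[a][pi, :] for pi in batch], axis=1)
                 for a in classes[:-1]}
            E[classes[-1]] = np.concatenate(
                [E0_last[pi, :] for pi in batch], axis=1)
            YE = {a: Y32 @ E[a] for a in classes[:-1]}
            ME = {a: M32 @ E[a] for a in classes[:-1]}
            YE[classes[-1]] = rowsum_Y[:, None] - sum(YE[a] for a in classes[:-1])
            ME[classes[-1]] = rowsum_M[:, None] - sum(ME[a] for a in classes[:-1])
            sums, counts = [], []
            for (a, b) in layout.combos:
                s = np.einsum("im,im->m", E[a], YE[b])
                c = np.einsum("im,im->m", E[a], ME[b])
                if layout.symmetric and a == b:
                    s, c = s / 2.0, c / 2.0
                sums.append(s)
                counts.append(c)
            sums = np.array(sums, dtype=np.float64)
            counts = np.rint(np.array(counts, dtype=np.float64))
            with np.errstate(divide="ignore", invalid="ignore"):
                rss1 = ss_tot - np.where(
                    counts > 0, sums ** 2 / np.where(counts > 0, counts, 1), 0.0
                ).sum(axis=0)
            lr = n_pairs * np.log(
                max(rss0, np.finfo(float).tiny) / np.maximum(rss1, eps))
            lr = np.maximum(lr, 0.0)
            sparse = ((counts > 0) & (counts < min_count)).any(axis=0)
            if sparse.any():
                for flat in np.flatnonzero(sparse):
                    pi, mi = divmod(int(flat), m)
                    g = G[batch[pi], mi]
                    lr[flat] = scan_marker(
                        y, g[pd_data.iL], g[pd_data.iS], layout, min_count
                    ).lr
            np.maximum(max_lr[start:start + p],
                       lr.reshape(p, m).max(axis=1),
                       out=max_lr[start:start + p])
    if not np.isfinite(max_lr).all():
        raise ValueError("no informative markers for permutation scan")
    return max_lr


def _permutation_max_lr(
    pd_data: _PairData, genotypes: np.ndarray, segregation: np.ndarray,
    descriptor: str, n_perm: int, seed, min_count: int = 2,
    chunk: int = 64,
) -> np.ndarray:
    """Genome-wide max LR for each of ``n_perm`` individual permutations.

    Permutations are batched: the class-indicator matrices of a chunk of
    permutations are stacked column-wise so each (value x indicator)
    product is a single large matmul.
    """
    rng = np.random.default_rng(seed)
    n = pd_data.n
    perms = [rng.permutation(n) for _ in range(n_perm)]
    path = (_perm_max_lr_complete if (genotypes >= 0).all()
            else _perm_max_lr_general)
    return path(pd_data, genotypes, segregation, descriptor, perms,
                min_count, chunk)


def _perm_max_lr_general(
    pd_data: _PairData, genotypes: np.ndarray, segregation: np.ndarray,
    descriptor: str, perms: list, min_count: int = 2, chunk: int = 64,
) -> np.ndarray:
    """Permutation max-LR general path (handles missing genotypes)."""
    n_perm = len(perms)
    max_lr = np.full(n_perm, -np.inf)

    for seg in (TESTCROSS, INTERCROSS):
        cols = np.flatnonzero(segregation == seg)
        if cols.size == 0:
            continue
        layout = ComboLayout(descriptor, seg)
        Y, Y2, M = pd_data.value_matrices(layout.symmetric)
        G = genotypes[:, cols]
        m = cols.size
        E0 = {a: (G == a).astype(float) for a in layout.classes}
        for start in range(0, n_perm, chunk):
            batch = perms[start:start + chunk]
            p = len(batch)
            E = {
                a: np.concatenate([E0[a][pi, :] for pi in batch], axis=1)
                for a in layout.classes
            }
            sums, sumsqs, counts = _combo_stats_block(E, Y, Y2, M, layout)
            lr = _lr_vector(sums, sumsqs, counts, min_count)[0]
            np.maximum(max_lr[start:start + p], lr.reshape(p, m).max(axis=1),
                       out=max_lr[start:start + p])
    if not np.isfinite(max_lr).all():
        raise ValueError("no informative markers for permutation scan")
    return max_lr


def permutation_threshold(
    pair_table: PairTable,
    ms: MarkerSet,
    descriptor: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed=0,
    min_count: int = 2,
) -> float:
    """Genome-wide LR threshold from individual-level permutations.

    Individual identities are permuted against the genotype matrix (each
    individual keeps its whole-genome genotype vector), the pair-genotype
    combinations are rebuilt against the fixed pair phenotypes, and the
    threshold is the empirical (1-alpha) quantile (the
    ``ceil((1-alpha)*n_perm)``-th order statistic) of the genome-wide
    maximum LR.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if alpha * n_perm < 1:
        raise ValueError(
            f"n_perm={n_perm} too small to estimate the {1 - alpha:.4g} "
            "quantile"
        )
    pdat = _PairData(pair_table, descriptor, ms.individuals)
    max_lr = _permutation_max_lr(
        pdat, ms.genotypes, ms.segregation, descriptor, n_perm, seed,
        min_count,
    )
    k = int(np.ceil((1.0 - alpha) * n_perm))
    return float(np.sort(max_lr)[k - 1])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class InteractionScanModel:
    """Genome scan model: pair descriptor phenotypes vs genotype combos.

    Parameters
    ----------
    pair_table
        Descriptor table from :func:`socialqtl.descriptors.build_pair_table`.
    marker_set
        Genotypes + linkage map of the family.
    descriptor
        ``mu``, ``an``, ``ag`` or ``al``; picks the phenotype column and
        whether combinations are symmetric.
    """

    def __init__(self, pair_table: PairTable, marker_set: MarkerSet,
                 descriptor: str):
        if descriptor not in SYMMETRIC_DESCRIPTORS | DIRECTIONAL_DESCRIPTORS:
            raise ValueError(f"unknown descriptor {descriptor!r}")
        self.pair_table = pair_table
        self.marker_set = marker_set
        self.descriptor = descriptor
        self._pair_data = _PairData(pair_table, descriptor,
                                    marker_set.individuals)

    def fit(self, alpha: float = 0.05, n_perm: int = 1000, seed=0,
            min_count: int = 2,
            merge_window_cM: float = 5.0) -> "InteractionScanResults":
        """Scan every informative marker and set the permutation threshold.

        Adjacent significant markers within ``merge_window_cM`` on the same
        chromosome merge into one QTL (peak marker reported).
        """
        ms = self.marker_set
        informative = ms.informative_mask()
        if not informative.any():
            warnings.warn("no informative markers; empty scan result")
        lr = np.full(ms.m, np.nan)
        if informative.any():
            lr[informative] = _scan_all_markers(
                self._pair_data, ms.genotypes[:, informative],
                ms.segregation[informative], self.descriptor, min_count,
            )
            threshold = permutation_threshold(
                self.pair_table, ms, self.descriptor, alpha, n_perm, seed,
                min_count,
            )
        else:
            threshold = np.inf
        return InteractionScanResults(
            model=self, lr=lr, threshold=threshold, min_count=min_count,
            alpha=alpha, n_perm=n_perm, seed=seed,
            merge_window_cM=merge_window_cM,
        )


@dataclass
class InteractionScanResults:
    """Per-marker scan statistics, genome-wide threshold and QTL calls."""

    model: InteractionScanModel
    lr: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    seed: object
    merge_window_cM: float
    min_count: int = 2
    _table: pd.DataFrame = field(default=None, repr=False)

    @property
    def table(self) -> pd.DataFrame:
        """Per-marker scan table (marker, chrom, pos_cM, LR, significant)."""
        if self._table is None:
            ms = self.model.marker_set
            sig = np.where(np.isnan(self.lr), False, self.lr > self.threshold)
            self._table = pd.DataFrame({
                "marker": ms.markers,
                "chrom": ms.gmap["chrom"].to_numpy(),
                "pos_cM": ms.gmap["pos_cM"].to_numpy(),
                "segregation": ms.segregation,
                "LR": self.lr,
                "significant": sig,
            })
        return self._table

    @property
    def significant_markers(self) -> list:
        t = self.table
        return t.loc[t["significant"], "marker"].tolist()

    @property
    def qtl(self) -> pd.DataFrame:
        """Merged QTL: runs of significant markers within the merge window."""
        t = self.table[self.table["significant"]].sort_values(
            ["chrom", "pos_cM"], kind="stable"
        )
        rows = []
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy()
            breaks = np.flatnonzero(np.diff(pos) > self.merge_window_cM)
            start = 0
            for stop in list(breaks + 1) + [len(sub)]:
                seg = sub.iloc[start:stop]
                peak = seg.loc[seg["LR"].idxmax()]
                rows.append((peak["marker"], chrom, peak["pos_cM"],
                             float(peak["LR"]), len(seg)))
                start = stop
        return pd.DataFrame(
            rows, columns=["peak_marker", "chrom", "pos_cM", "LR", "n_markers"]
        )

    def marker_detail(self, marker) -> MarkerScan:
        """Combo means/counts at one marker (computed on demand)."""
        ms = self.model.marker_set
        j = ms.marker_index(marker)
        if ms.segregation[j] == "uninformative":
            raise ValueError(f"marker {marker!r} is uninformative")
        layout = ComboLayout(self.model.descriptor, ms.segregation[j])
        g = ms.genotypes[:, j]
        pdat = self.model._pair_data
        return scan_marker(pdat.y, g[pdat.iL], g[pdat.iS], layout,
                           self.min_count)

    def summary(self) -> str:
        qtl = self.qtl
        lines = [
            f"Interaction-QTL scan: descriptor {self.model.descriptor!r}, "
            f"{self.model.marker_set.m} markers, "
            f"{self.model.marker_set.n} individuals, "
            f"{self.model._pair_data.n_pairs} pairs",
            f"  genome-wide threshold (alpha={self.alpha}, "
            f"{self.n_perm} permutations): LR > {self.threshold:.3f}",
            f"  significant markers: {len(self.significant_markers)}",
            f"  merged QTL ({self.merge_window_cM} cM window): {len(qtl)}",
        ]
        for _, row in qtl.iterrows():
            lines.append(
                f"    {row['peak_marker']}  chr {row['chrom']} @ "
                f"{row['pos_cM']:.2f} cM  LR={row['LR']:.2f} "
                f"({row['n_markers']} markers)"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# traditional comparator: individual-phenotype single-marker ANOVA scan
# ---------------------------------------------------------------------------

def traditional_scan(
    phenotypes: np.ndarray,
    ms: MarkerSet,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed=0,
) -> pd.DataFrame:
    """One-way genotype-mean ANOVA scan on individual phenotypes.

    The comparator for the pair-based model: LR = n*ln(RSS0/RSS1) over an
    individual's own genotype groups at each marker, with the same
    genome-wide permutation threshold machinery (here the phenotype vector
    is permuted against the genotype matrix, which is the individual-level
    exchangeability in this model).  Returns the per-marker table with a
    ``significant`` column; the threshold is in ``df.attrs['threshold']``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = np.asarray(phenotypes, dtype=float)
    if y.shape[0] != ms.n:
        raise ValueError("phenotype length does not match marker set")

    def _all_lr(yvec):
        lr = np.full(ms.m, np.nan)
        ss_tot_all = None
        for seg, k in ((TESTCROSS, 2), (INTERCROSS, 3)):
            cols = np.flatnonzero(ms.segregation == seg)
            if cols.size == 0:
                continue
            G = ms.genotypes[:, cols]
            sums = np.zeros((k, cols.size))
            sumsqs = np.zeros((k, cols.size))
            counts = np.zeros((k, cols.size))
            for a in range(k):
                Ea = (G == a)
                sums[a] = yvec @ Ea
                sumsqs[a] = (yvec ** 2) @ Ea
                counts[a] = Ea.sum(axis=0)
            lr[cols] = _lr_vector(sums, sumsqs, counts, min_count=2)[0]
        return lr

    lr_obs = _all_lr(y)
    rng = np.random.default_rng(seed)
    max_lr = np.empty(n_perm)
    for p in range(n_perm):
        max_lr[p] = np.nanmax(_all_lr(y[rng.permutation(ms.n)]))
    k = int(np.ceil((1.0 - alpha) * n_perm))
    threshold = float(np.sort(max_lr)[k - 1])
    out = pd.DataFrame({
        "marker": ms.markers,
        "chrom": ms.gmap["chrom"].to_numpy(),
        "pos_cM": ms.gmap["pos_cM"].to_numpy(),
        "LR": lr_obs,
        "significant": np.where(np.isnan(lr_obs), False, lr_obs > threshold),
    })
    out.attrs["threshold"] = threshold
    return out
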