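"""Genotype, linkage-map and phenotype I/O for one full-sib family.

Genotype coding follows the two mapping-informative segregation patterns of
an F1 full-sib cross:

* testcross markers (informative in one parent) segregate two offspring
  genotypes 1:1, coded ``0`` (homozygote) / ``1`` (heterozygote);
* intercross markers (informative in both parents) segregate three
  genotypes 1:2:1, coded ``0/1/2`` for ``aa/ab/bb``.

Missing genotypes are coded ``-1``.  Markers whose observed codes fit
neither pattern (e.g. monomorphic columns) are classed *uninformative* and
excluded from scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerSet",
    "SegregationReport",
    "load_genotypes",
    "load_map",
    "classify_segregation",
    "write_run_metadata",
]

MISSING = -1

TESTCROSS = "testcross"
INTERCROSS = "intercross"
UNINFORMATIVE = "uninformative"


def _infer_segregation(column: np.ndarray) -> str:
    vals = set(np.unique(column[column != MISSING]).tolist())
    if vals == {0, 1}:
        return TESTCROSS
    if vals == {0, 1, 2}:
        return INTERCROSS
    return UNINFORMATIVE


@dataclass
class MarkerSet:
    """Genotypes, linkage map and per-marker segregation for one family.

    Attributes
    ----------
    individuals : list
        Ordered individual ids (n >= 2).
    markers : list
        Ordered marker ids; sorted by (chromosome, position) on load.
    genotypes : ndarray of int8, shape (n, m)
        Codes as described in the module docstring; ``-1`` = missing.
    gmap : pandas.DataFrame
        Columns ``marker, chrom, pos_cM`` aligned with ``markers``.
    segregation : ndarray of str, shape (m,)
        Per-marker type: testcross / intercross / uninformative.
    """

    individuals: list
    markers: list
    genotypes: np.ndarray
    gmap: pd.DataFrame
    segregation: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if n < 2:
            raise ValueError("a marker set needs at least 2 individuals")
        if len(self.individuals) != n or len(self.markers) != m:
            raise ValueError("genotype matrix shape does not match id lists")
        if list(self.gmap["marker"]) != list(self.markers):
            raise ValueError("linkage map and genotype markers disagree")
        for chrom, sub in self.gmap.groupby("chrom", sort=False):
            if not sub["pos_cM"].is_monotonic_increasing:
                raise ValueError(
                    f"map positions not nondecreasing on chromosome {chrom}"
                )
        valid = (self.genotypes >= MISSING) & (self.genotypes <= 2)
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[tuple(bad)]} for "
                f"individual {self.individuals[bad[0]]} at marker "
                f"{self.markers[bad[1]]}"
            )
        if self.segregation is None:
            self.segregation = np.array(
                [_infer_segregation(self.genotypes[:, j])
                 for j in range(m)], dtype=object
            )

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def informative_mask(self) -> np.ndarray:
        return self.segregation != UNINFORMATIVE

    def marker_index(self, marker) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in marker set") from None

    def column(self, marker) -> np.ndarray:
        return self.genotypes[:, self.marker_index(marker)]

    def sorted_by_map(self) -> "MarkerSet":
        order = self.gmap.sort_values(
            ["chrom", "pos_cM"], kind="stable"
        ).index.to_numpy()
        return MarkerSet(
            individuals=list(self.individuals),
            markers=[self.markers[j] for j in order],
            genotypes=self.genotypes[:, order],
            gmap=self.gmap.iloc[order].reset_index(drop=True),
            segregation=self.segregation[order],
        )

    # -- round-trippable text output ------------------------------------
    def write(self, genotype_path, map_path) -> None:
        df = pd.DataFrame(self.genotypes, columns=self.markers)
        df = df.astype(object).mask(df == MISSING, "NA")
        df.insert(0, "individual_id", self.individuals)
        df.to_csv(genotype_path, sep="\t", index=False)
        out = self.gmap.copy()
        out["segregation"] = self.segregation
        out.to_csv(map_path, sep="\t", index=False)


def load_map(path, sep: str = "\t") -> pd.DataFrame:
    gmap = pd.read_csv(path, sep=sep)
    for col in ("marker", "chrom", "pos_cM"):
        if col not in gmap.columns:
            raise ValueError(f"map file {path} missing column {col!r}")
    dup = gmap["marker"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicated marker ids in {path}: "
            f"{gmap.loc[dup, 'marker'].tolist()}"
        )
    return gmap[[c for c in gmap.columns]]


def _load_delimited(path, map_df: pd.DataFrame, sep: str) -> MarkerSet:
    df = pd.read_csv(path, sep=sep, na_values=["NA"], dtype={0: str})
    if df.columns[0] != "individual_id":
        raise ValueError(
            f"{path}: first column must be 'individual_id', "
            f"got {df.columns[0]!r}"
        )
    markers = list(df.columns[1:])
    dup = pd.Index(markers).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated marker columns")
    known = set(map_df["marker"])
    unknown = [mk for mk in markers if mk not in known]
    if unknown:
        raise ValueError(
            f"{path}: markers missing from map: {unknown[:5]}"
        )
    geno = df[markers].to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno)
    if not np.all(np.equal(np.mod(geno, 1), 0)):
        row, col = np.argwhere(np.mod(geno, 1) != 0)[0]
        raise ValueError(
            f"{path}: non-integer genotype code at line {row + 2}, "
            f"marker {markers[col]}"
        )
    gmap = map_df.set_index("marker").loc[markers].reset_index()
    order = gmap.sort_values(["chrom", "pos_cM"], kind="stable").index
    return MarkerSet(
        individuals=list(df["individual_id"]),
        markers=[markers[j] for j in order],
        genotypes=geno.astype(np.int8)[:, order],
        gmap=gmap.iloc[order][["marker", "chrom", "pos_cM"]]
            .reset_index(drop=True),
    )


def _load_vcf(path, map_df: pd.DataFrame) -> MarkerSet:
    """Biallelic-SNP VCF to genotype codes via the GT field.

    Offspring dosage of the alternate allele maps to 0/1/2; a marker whose
    observed codes are {0,1} only is typed testcross downstream.  Parental
    columns named ``parent1``/``parent2``, when present, are used only to
    set the segregation type and are excluded from the offspring matrix.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    parents = [s for s in samples if s in ("parent1", "parent2")]
    offspring = [s for s in samples if s not in parents]
    keep = [samples.index(s) for s in offspring]
    pidx = [samples.index(s) for s in parents]

    markers, rows, seg = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: non-biallelic record at {var.ID}")
        mk = var.ID or f"{var.CHROM}:{var.POS}"
        gts = var.genotype.array()
        dose = np.where((gts[:, :2] < 0).any(axis=1), MISSING,
                        gts[:, :2].clip(min=0).sum(axis=1))
        markers.append(mk)
        rows.append(dose[keep])
        if len(pidx) == 2:
            het = [0 < dose[i] < 2 for i in pidx]
            seg.append(INTERCROSS if all(het)
                       else TESTCROSS if any(het) else UNINFORMATIVE)
        else:
            seg.append(None)
    geno = np.array(rows, dtype=np.int8).T
    gmap = map_df.set_index("marker").loc[markers].reset_index()
    order = gmap.sort_values(["chrom", "pos_cM"], kind="stable").index
    segregation = None
    if all(s is not None for s in seg):
        segregation = np.array(seg, dtype=object)[order]
    return MarkerSet(
        individuals=offspring,
        markers=[markers[j] for j in order],
        genotypes=geno[:, order],
        gmap=gmap.iloc[order][["marker", "chrom", "pos_cM"]]
            .reset_index(drop=True),
        segregation=segregation,
    )


def load_genotypes(path, map_path, fmt: str = "delimited",
                   sep: str = "\t") -> MarkerSet:
    """Load a genotype matrix plus linkage map into a validated MarkerSet.

    ``fmt`` is ``"delimited"`` (tab-separated, first column
    ``individual_id``, missing = ``NA``) or ``"vcf"``.
    """
    map_df = load_map(map_path, sep=sep)
    if fmt == "delimited":
        return _load_delimited(path, map_df, sep)
    if fmt == "vcf":
        return _load_vcf(path, map_df)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# segregation check
# ---------------------------------------------------------------------------

@dataclass
class SegregationReport:
    """Per-marker goodness of fit to the Mendelian segregation ratio."""

    table: pd.DataFrame  # marker, segregation, counts, chi2, p, distorted
    alpha: float

    @property
    def n_distorted(self) -> int:
        return int(self.table["distorted"].sum())


_EXPECTED = {TESTCROSS: np.array([0.5, 0.5]),
             INTERCROSS: np.array([0.25, 0.5, 0.25])}


def classify_segregation(ms: MarkerSet, alpha: float = 0.01) -> SegregationReport:
    """Chi-square test of 1:1 (testcross) / 1:2:1 (intercross) per marker.

    Distorted markers are flagged, never removed.
    """
    rows = []
    for j, mk in enumerate(ms.markers):
        seg = ms.segregation[j]
        col = ms.genotypes[:, j]
        col = col[col != MISSING]
        if seg == UNINFORMATIVE:
            rows.append((mk, seg, tuple(), np.nan, np.nan, False))
            continue
        k = 2 if seg == TESTCROSS else 3
        counts = np.bincount(col, minlength=k)[:k]
        chi2, p = stats.chisquare(counts, f_exp=_EXPECTED[seg] * counts.sum())
        rows.append((mk, seg, tuple(int(c) for c in counts),
                     float(chi2), float(p), bool(p < alpha)))
    table = pd.DataFrame(
        rows, columns=["marker", "segregation", "counts", "chi2", "p",
                       "distorted"]
    )
    return SegregationReport(table=table, alpha=alpha)


def write_run_metadata(path, **params) -> None:
    """JSON sidecar recording the parameters/seeds that produced a result."""
    import socialqtl

    meta = {"package": "socialqtl", "version": socialqtl.__version__}
    meta.update(params)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
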