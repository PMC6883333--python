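"""Pairwise interaction descriptors for co-cultured populations.

For an ordered pair with a larger member L (phenotype ``w_L``) and a smaller
member S (``w_S``), four scalar descriptors quantify the strength of the
social interaction between them:

* mutualism    ``z_mu = w_L * w_S / (w_L - w_S)`` — the product of phenotypes
  (similarity begets cooperation), normalised by the phenotypic difference;
* antagonism   ``z_an = 1 / (w_L * w_S * (w_L - w_S))`` — the inverse product,
  likewise normalised;
* aggression   ``z_ag = w_L / w_S`` — how much the larger member dominates;
* altruism     ``z_al = 1 - w_S / w_L`` — the relative size deficit the larger
  member tolerates in its partner.

``z_mu`` and ``z_an`` are symmetric in the two members and undefined for an
exact tie (division by zero); ``z_ag`` and ``z_al`` are directional,
attaching to the ordered pair (larger -> smaller), and degenerate gracefully
to ``z_ag = 1``, ``z_al = 0`` at a tie.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PairDescriptors",
    "PairTable",
    "compute_pair_descriptors",
    "build_pair_table",
    "read_phenotypes",
]

#: Default relative tolerance below which |w_L - w_S| counts as a tie.
DEFAULT_TIE_TOLERANCE = 1e-8


@dataclass(frozen=True)
class PairDescriptors:
    """The four interaction descriptors for one ordered pair.

    ``z_mu``/``z_an`` are ``nan`` (and ``defined_mu_an`` False) when the two
    phenotypes tie within tolerance.
    """

    w_L: float
    w_S: float
    z_ag: float
    z_al: float
    z_mu: float = float("nan")
    z_an: float = float("nan")
    defined_mu_an: bool = True


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"phenotype {name}={value!r} must be positive and finite")


def compute_pair_descriptors(
    w_a: float,
    w_b: float,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> PairDescriptors:
    """Compute the four descriptors for one pair of phenotypes.

    The pair is ordered internally: ``w_L = max(w_a, w_b)``,
    ``w_S = min(w_a, w_b)``, so the function is symmetric in its arguments.
    When ``|w_L - w_S| <= tie_tolerance * w_L`` the mutualism and antagonism
    descriptors are left undefined (``defined_mu_an=False``) while
    ``z_ag = 1`` and ``z_al = 0``.
    """
    _check_positive("w_a", w_a)
    _check_positive("w_b", w_b)
    w_L, w_S = (w_a, w_b) if w_a >= w_b else (w_b, w_a)
    diff = w_L - w_S
    if diff <= tie_tolerance * w_L:
        return PairDescriptors(w_L=w_L, w_S=w_S, z_ag=1.0, z_al=0.0,
                               defined_mu_an=False)
    prod = w_L * w_S
    return PairDescriptors(
        w_L=w_L,
        w_S=w_S,
        z_ag=w_L / w_S,
        z_al=1.0 - w_S / w_L,
        z_mu=prod / diff,
        z_an=1.0 / (prod * diff),
        defined_mu_an=True,
    )


class PairTable:
    """Descriptor table over every unordered pair of a population.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per unordered pair with columns ``id_L, id_S, w_L, w_S,
        z_mu, z_an, z_ag, z_al, defined_mu_an``.  ``id_L`` is always the
        larger member (ties keep input order).
    n_ties : int
        Number of pairs flagged as ties (mutualism/antagonism undefined).
    """

    COLUMNS = ["id_L", "id_S", "w_L", "w_S",
               "z_mu", "z_an", "z_ag", "z_al", "defined_mu_an"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"pair table missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_ties(self) -> int:
        return int((~self.table["defined_mu_an"]).sum())

    @property
    def individuals(self) -> list:
        ids = pd.unique(
            pd.concat([self.table["id_L"], self.table["id_S"]], ignore_index=True)
        )
        return sorted(ids)

    def symmetric_view(self) -> pd.DataFrame:
        """Mutualism/antagonism values keyed by unordered pair.

        Tie-flagged pairs (descriptor undefined) are excluded.
        """
        t = self.table[self.table["defined_mu_an"]]
        return t[["id_L", "id_S", "z_mu", "z_an"]].copy()

    def directional_view(self) -> pd.DataFrame:
        """Aggression/altruism keyed by the ordered (larger, smaller) pair."""
        return self.table[["id_L", "id_S", "z_ag", "z_al"]].copy()

    def values_for(self, descriptor: str) -> pd.DataFrame:
        """Rows (id_L, id_S, value) for one descriptor kind.

        ``descriptor`` is one of ``mu, an, ag, al``.  For ``mu``/``an`` the
        tie-flagged pairs are dropped.
        """
        col = {"mu": "z_mu", "an": "z_an", "ag": "z_ag", "al": "z_al"}[descriptor]
        t = self.table
        if descriptor in ("mu", "an"):
            t = t[t["defined_mu_an"]]
        out = t[["id_L", "id_S", col]].rename(columns={col: "value"})
        return out.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "PairTable":
        return cls(pd.read_csv(path, sep="\t"))


def build_pair_table(
    phenotypes: Mapping,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    prescale: bool = False,
) -> PairTable:
    """Build the full pair-descriptor table for a population.

    Parameters
    ----------
    phenotypes
        Mapping from individual id to a positive trait value.
    tie_tolerance
        Relative tolerance for flagging tied pairs.
    prescale
        If True, divide all trait values by the population mean first
        (useful when traits from different units are compared); off by
        default — descriptors are defined on raw trait values.
    """
    ids = list(phenotypes)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals to form pairs")
    values = {i: float(phenotypes[i]) for i in ids}
    for i, v in values.items():
        _check_positive(f"phenotype[{i!r}]", v)
    if prescale:
        mean = float(np.mean(list(values.values())))
        values = {i: v / mean for i, v in values.items()}

    rows = []
    for a, b in combinations(ids, 2):
        wa, wb = values[a], values[b]
        d = compute_pair_descriptors(wa, wb, tie_tolerance)
        id_L, id_S = (a, b) if wa >= wb else (b, a)
        rows.append((id_L, id_S, d.w_L, d.w_S,
                     d.z_mu, d.z_an, d.z_ag, d.z_al, d.defined_mu_an))
    table = pd.DataFrame(rows, columns=PairTable.COLUMNS)
    return PairTable(table)


def read_phenotypes(path, sep: str = "\t") -> dict:
    """Read an ``individual_id`` / ``trait`` phenotype table into a dict."""
    df = pd.read_csv(path, sep=sep)
    for col in ("individual_id", "trait"):
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} missing column {col!r}")
    dup = df["individual_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate individual ids in {path}: "
            f"{df.loc[dup, 'individual_id'].tolist()}"
        )
    return dict(zip(df["individual_id"], df["trait"].astype(float)))
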