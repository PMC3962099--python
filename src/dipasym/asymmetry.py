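"""Dipeptide/antidipeptide asymmetry statistics: c190, propensities, reports.

For an unordered residue pair {A, B} with A != B, the asymmetry statistic is

    c190 = |n_AB - n_BA| / ((n_AB + n_BA) / 2)

the absolute count difference relative to the mean count, reported on a x100
scale so that values match the conventional tables (0 for perfectly balanced
pairs, 200 when one orientation is never observed).  There are 190 such
unordered pairs; same-residue pairs carry no orientation and are ignored.
The signed variant drops the absolute value and is reported in the
alphabetical orientation of the pair, so its sign says which orientation
dominates.

The propensity of an ordered dipeptide BJ,

    P(BJ) = (n_BJ / n_XJ) / (n_BX / n_XX),

is the enrichment of B immediately preceding J relative to independence of
the two positions (X = any residue).

Zero denominators are flagged as undefined and excluded from averages and
rankings, never silently zeroed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .counting import AA_TO_INDEX, N_RESIDUES, DipeptideCountTable
from .sequence_io import STANDARD_RESIDUES

#: The 190 unordered distinct pairs in canonical (alphabetical) orientation.
UNORDERED_PAIRS: List[Tuple[str, str]] = [
    (a, b) for a, b in itertools.combinations(STANDARD_RESIDUES, 2)
]
PAIR_LABELS: List[str] = [a + b for a, b in UNORDERED_PAIRS]

# index arrays for vectorised extraction of (n_AB, n_BA) from a 20x20 matrix
_IU, _JU = np.triu_indices(N_RESIDUES, k=1)


def c190(n_ab: int, n_ba: int) -> float:
    """Asymmetry of an unordered pair from its two ordered counts (x100 scale)."""
    total = n_ab + n_ba
    if total <= 0:
        raise ValueError("c190 is undefined when both counts are zero")
    return 200.0 * abs(n_ab - n_ba) / total


def signed_c190(n_ab: int, n_ba: int) -> float:
    """Signed asymmetry: positive when AB (first argument) dominates."""
    total = n_ab + n_ba
    if total <= 0:
        raise ValueError("signed c190 is undefined when both counts are zero")
    return 200.0 * (n_ab - n_ba) / total


def propensity_difference(p_ab: float, p_ba: float) -> float:
    """Absolute difference between a dipeptide's and its antidipeptide's propensity."""
    return abs(p_ab - p_ba)


@dataclass(frozen=True)
class PairAsymmetry:
    """Counts and asymmetry for one unordered pair, alphabetical orientation."""

    first: str   # alphabetically first residue
    second: str
    n_ab: int    # count with `first` preceding `second`
    n_ba: int

    @property
    def pair(self) -> str:
        return self.first + self.second

    @property
    def defined(self) -> bool:
        return self.n_ab + self.n_ba > 0

    @property
    def c190(self) -> float:
        return c190(self.n_ab, self.n_ba)

    @property
    def signed_c190(self) -> float:
        return signed_c190(self.n_ab, self.n_ba)


class AsymmetryTable:
    """The 190 per-pair asymmetries computed from a count table."""

    def __init__(self, entries: Dict[Tuple[str, str], PairAsymmetry]):
        if set(entries) != set(UNORDERED_PAIRS):
            raise ValueError("an AsymmetryTable must contain exactly the 190 pairs")
        self.entries = entries

    @classmethod
    def from_counts(cls, table: DipeptideCountTable) -> "AsymmetryTable":
        c = table.counts
        entries = {
            (a, b): PairAsymmetry(
                a, b, int(c[AA_TO_INDEX[a], AA_TO_INDEX[b]]),
                int(c[AA_TO_INDEX[b], AA_TO_INDEX[a]]),
            )
            for a, b in UNORDERED_PAIRS
        }
        return cls(entries)

    def __getitem__(self, pair: Union[str, Tuple[str, str]]) -> PairAsymmetry:
        a, b = tuple(pair)
        return self.entries[tuple(sorted((a, b)))]

    def __iter__(self):
        return (self.entries[p] for p in UNORDERED_PAIRS)

    def defined_entries(self) -> List[PairAsymmetry]:
        return [e for e in self if e.defined]

    def to_frame(self) -> pd.DataFrame:
        """190-row report: pair, counts, c190, signed c190 (NaN when undefined)."""
        rows = []
        for e in self:
            rows.append(
                {
                    "pair": e.pair,
                    "n_ab": e.n_ab,
                    "n_ba": e.n_ba,
                    "c190": e.c190 if e.defined else np.nan,
                    "signed_c190": e.signed_c190 if e.defined else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("pair")


def asymmetry_table(table: DipeptideCountTable) -> AsymmetryTable:
    """One asymmetry entry per unordered distinct pair of a count table."""
    return AsymmetryTable.from_counts(table)


def pair_c190_vector(counts: np.ndarray, signed: bool = False) -> np.ndarray:
    """Vectorised c190 over the 190 pairs of one or more flat count vectors.

    ``counts`` has shape (400,) or (k, 400); returns shape (190,) or (k, 190)
    aligned with :data:`PAIR_LABELS`, NaN where both counts are zero.
    """
    arr = np.asarray(counts, dtype=np.float64)
    squeeze = arr.ndim == 1
    mat = arr.reshape(-1, N_RESIDUES, N_RESIDUES)
    n_ab = mat[:, _IU, _JU]
    n_ba = mat[:, _JU, _IU]
    total = n_ab + n_ba
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = n_ab - n_ba if signed else np.abs(n_ab - n_ba)
        out = np.where(total > 0, 200.0 * diff / total, np.nan)
    return out[0] if squeeze else out


class PropensityTable:
    """The 400 ordered-pair propensities P(BJ), with an undefined-entry mask."""

    def __init__(self, values: np.ndarray, defined: np.ndarray):
        self.values = np.asarray(values, dtype=np.float64)
        self.defined = np.asarray(defined, dtype=bool)
        if self.values.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("propensity table must be 20x20")

    @classmethod
    def from_counts(cls, table: DipeptideCountTable) -> "PropensityTable":
        c = table.counts.astype(np.float64)
        n_first = c.sum(axis=1)   # n_BX
        n_second = c.sum(axis=0)  # n_XJ
        n_total = c.sum()
        defined = (n_first[:, None] > 0) & (n_second[None, :] > 0) & (n_total > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = (c / n_second[None, :]) / (n_first[:, None] / n_total)
        values = np.where(defined, values, np.nan)
        return cls(values, defined)

    def __getitem__(self, pair: Union[str, Tuple[str, str]]) -> float:
        b, j = tuple(pair)
        i, k = AA_TO_INDEX[b], AA_TO_INDEX[j]
        if not self.defined[i, k]:
            raise ValueError(f"propensity P({b}{j}) is undefined (zero marginal)")
        return float(self.values[i, k])

    def to_frame(self) -> pd.DataFrame:
        """400-row report: ordered pair, propensity (NaN when undefined)."""
        idx = list(STANDARD_RESIDUES)
        rows = [
            {"pair": b + j, "propensity": self.values[i, k]}
            for i, b in enumerate(idx)
            for k, j in enumerate(idx)
        ]
        return pd.DataFrame(rows).set_index("pair")


def propensity(table: DipeptideCountTable, first: str, second: str) -> float:
    """P(first, second) = (n_BJ / n_XJ) / (n_BX / n_XX) from a count table."""
    return PropensityTable.from_counts(table)[first, second]


@dataclass(frozen=True)
class ResidueAverage:
    """Mean c190 over the (up to) 19 defined pairs containing one residue."""

    residue: str
    mean_c190: float
    std_error: float
    n_pairs: int  # defined pairs entering the average

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


def residue_averages(at: AsymmetryTable) -> List[ResidueAverage]:
    """Per-residue mean and standard error of c190 over pairs containing it.

    Undefined pairs are excluded with the divisor reduced; the standard error
    uses the n-1 sample standard deviation over sqrt(n), reported as 0 when a
    single value remains.
    """
    out = []
    for res in STANDARD_RESIDUES:
        values = [
            e.c190 for e in at if e.defined and res in (e.first, e.second)
        ]
        n = len(values)
        if n == 0:
            out.append(ResidueAverage(res, float("nan"), float("nan"), 0))
        elif n == 1:
            out.append(ResidueAverage(res, values[0], 0.0, 1))
        else:
            arr = np.asarray(values)
            out.append(
                ResidueAverage(
                    res,
                    float(arr.mean()),
                    float(arr.std(ddof=1) / np.sqrt(n)),
                    n,
                )
            )
    return out


def residue_average_frame(at: AsymmetryTable, decimals: int = 2) -> pd.DataFrame:
    """Residue-average report with a formatted "mean(SE)" column."""
    rows = []
    for ra in residue_averages(at):
        formatted = (
            f"{ra.mean_c190:.{decimals}f}({ra.std_error:.{decimals}f})"
            if ra.defined
            else "undefined"
        )
        rows.append(
            {
                "residue": ra.residue,
                "mean_c190": ra.mean_c190,
                "std_error": ra.std_error,
                "n_pairs": ra.n_pairs,
                "mean(se)": formatted,
            }
        )
    return pd.DataFrame(rows).set_index("residue")


def rank_pairs(at: AsymmetryTable, top_k: int) -> List[PairAsymmetry]:
    """The top_k defined pairs by descending c190, ties broken alphabetically."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = sorted(at.defined_entries(), key=lambda e: (-e.c190, e.pair))
    return ranked[:top_k]
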