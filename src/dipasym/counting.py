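"""Ordered dipeptide and gapped-pair counting over protein sequence sets.

A pair at gap ``g`` is the ordered couple of residues at positions
``(i, i + g + 1)``; ``g = 0`` gives adjacent dipeptides AB, ``g = 5`` gives
the A(X)5B pairs used to probe whether asymmetry survives once the two
residues can no longer touch.  Windows overlap (step 1), so a sequence of
length L with no excluded letters contributes L - 1 - g pairs.

Only the two endpoint letters must be standard residues; intervening letters
at gap > 0 may be anything except the '*' separator, which no window may
cross.  A leading N-terminal methionine can optionally be removed before
counting (``skip_initial_met``), since database sequences retain it
inconsistently and it inflates MX counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Union

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_RESIDUES, SequenceSet

N_RESIDUES = 20
AA_TO_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}

_LOOKUP = np.full(256, -1, dtype=np.int16)
for _aa, _i in AA_TO_INDEX.items():
    _LOOKUP[ord(_aa)] = _i


def encode_residues(fragment: str) -> np.ndarray:
    """Map a residue string to indices 0..19; non-standard letters map to -1."""
    return _LOOKUP[np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)]


def _sequence_pair_counts(
    residues: str, gap: int, skip_initial_met: bool
) -> np.ndarray:
    """Flat 400-vector of ordered pair counts for one sequence."""
    counts = np.zeros(N_RESIDUES * N_RESIDUES, dtype=np.int64)
    if skip_initial_met and residues.startswith("M"):
        residues = residues[1:]
    step = gap + 1
    for frag in residues.split("*"):
        if len(frag) < step + 1:
            continue
        idx = encode_residues(frag)
        a = idx[: len(idx) - step]
        b = idx[step:]
        mask = (a >= 0) & (b >= 0)
        if mask.any():
            counts += np.bincount(
                a[mask] * N_RESIDUES + b[mask], minlength=N_RESIDUES * N_RESIDUES
            )
    return counts


class Marginals(NamedTuple):
    n_first: pd.Series   # n_AX per residue
    n_second: pd.Series  # n_XB per residue
    n_total: int         # n_XX


@dataclass
class DipeptideCountTable:
    """Ordered 20x20 pair counts at a fixed gap, with the counting policy recorded."""

    gap: int
    counts: np.ndarray  # (20, 20) int64; rows = first residue, cols = second
    n_sequences: int
    skip_initial_met: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("counts must be a 20x20 matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        """n_XX: total number of counted windows."""
        return int(self.counts.sum())

    def count(self, first: str, second: str) -> int:
        return int(self.counts[AA_TO_INDEX[first], AA_TO_INDEX[second]])

    def marginals(self) -> Marginals:
        """Row sums (n_AX), column sums (n_XB) and the grand total n_XX."""
        idx = list(STANDARD_RESIDUES)
        return Marginals(
            n_first=pd.Series(self.counts.sum(axis=1), index=idx),
            n_second=pd.Series(self.counts.sum(axis=0), index=idx),
            n_total=self.n_total,
        )

    def __add__(self, other: "DipeptideCountTable") -> "DipeptideCountTable":
        if (self.gap, self.skip_initial_met) != (other.gap, other.skip_initial_met):
            raise ValueError("cannot add tables with different counting policies")
        return DipeptideCountTable(
            gap=self.gap,
            counts=self.counts + other.counts,
            n_sequences=self.n_sequences + other.n_sequences,
            skip_initial_met=self.skip_initial_met,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DipeptideCountTable):
            return NotImplemented
        return (
            self.gap == other.gap
            and self.skip_initial_met == other.skip_initial_met
            and self.n_sequences == other.n_sequences
            and bool((self.counts == other.counts).all())
        )

    def to_frame(self) -> pd.DataFrame:
        idx = list(STANDARD_RESIDUES)
        return pd.DataFrame(self.counts, index=idx, columns=idx)

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write the 20x20 table as TSV with a '#' metadata header."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(
                f"# dipeptide counts\tgap={self.gap}"
                f"\tskip_initial_met={int(self.skip_initial_met)}"
                f"\tn_sequences={self.n_sequences}\tn_xx={self.n_total}\n"
            )
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DipeptideCountTable":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header")
            meta = dict(
                item.split("=", 1) for item in header.split("\t") if "=" in item
            )
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        table = cls(
            gap=int(meta["gap"]),
            counts=frame.to_numpy(),
            n_sequences=int(meta["n_sequences"]),
            skip_initial_met=bool(int(meta["skip_initial_met"])),
        )
        if table.n_total != int(meta["n_xx"]):
            raise ValueError(f"{path}: n_xx header does not match table sum")
        return table


def count_pairs(
    seqs: Union[SequenceSet, Iterable],
    gap: int = 0,
    skip_initial_met: bool = False,
) -> DipeptideCountTable:
    """Count all ordered residue pairs at the given gap across a sequence set.

    An empty set yields an all-zero table; sequences shorter than ``gap + 2``
    contribute nothing.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    total = np.zeros(N_RESIDUES * N_RESIDUES, dtype=np.int64)
    n = 0
    for seq in seqs:
        total += _sequence_pair_counts(seq.residues, gap, skip_initial_met)
        n += 1
    return DipeptideCountTable(
        gap=gap,
        counts=total.reshape(N_RESIDUES, N_RESIDUES),
        n_sequences=n,
        skip_initial_met=skip_initial_met,
    )


def pair_count_matrix(
    seqs: Union[SequenceSet, Iterable],
    gap: int = 0,
    skip_initial_met: bool = False,
) -> np.ndarray:
    """Per-sequence flat pair counts, shape (n_sequences, 400).

    The row order follows the set's iteration order; summing rows reproduces
    :func:`count_pairs`.  Used by resampling procedures (bootstrap, FPPP-style
    subset statistics) that need to re-aggregate counts without rescanning
    sequences.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    rows = [_sequence_pair_counts(s.residues, gap, skip_initial_met) for s in seqs]
    if not rows:
        return np.zeros((0, N_RESIDUES * N_RESIDUES), dtype=np.int64)
    return np.vstack(rows)
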