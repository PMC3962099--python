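"""Sampling-sufficiency analysis by non-overlapping subsampling (FPPP).

The Fragmented Prediction Performance Plot procedure asks whether a
statistic computed on a sequence set is stable: the set is cut into
non-overlapping subsets of a given size, the statistic is recomputed on
each subset, and the mean and standard error across subsets are compared
across increasing subset sizes.  A statistic that is flat in the subset
size, with the full-set value inside the error band, is adequately sampled.

Also provides a sequence-level bootstrap for per-pair c190 standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .asymmetry import PAIR_LABELS, pair_c190_vector
from .counting import pair_count_matrix
from .sequence_io import SequenceSet


def partition(seqs: SequenceSet, subset_size: int, seed: int) -> List[SequenceSet]:
    """Cut a seeded random permutation of the set into disjoint chunks.

    Produces floor(N / subset_size) subsets of exactly ``subset_size``
    members; leftover sequences are discarded.  The same seed yields an
    identical partition.
    """
    n = len(seqs)
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds set size {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_subsets = n // subset_size
    out = []
    for j in range(n_subsets):
        chunk = perm[j * subset_size : (j + 1) * subset_size]
        out.append(
            SequenceSet(
                [seqs[int(i)] for i in chunk],
                label=f"{seqs.label}|subset{j}",
            )
        )
    return out


@dataclass
class FPPPResult:
    """Per-pair mean and standard error of c190 across subsets of one size."""

    subset_size: int
    n_subsets: int
    per_pair: pd.DataFrame  # index = pair, columns = mean_c190, std_error, n_defined
    seed: int


def _subset_c190_matrix(
    per_seq_counts: np.ndarray, perm: np.ndarray, subset_size: int
) -> np.ndarray:
    """(n_subsets, 190) c190 values from per-sequence counts, NaN if undefined."""
    n_subsets = len(perm) // subset_size
    subset_counts = np.stack(
        [
            per_seq_counts[perm[j * subset_size : (j + 1) * subset_size]].sum(axis=0)
            for j in range(n_subsets)
        ]
    )
    return pair_c190_vector(subset_counts)


def fppp_analysis(
    seqs: SequenceSet,
    subset_sizes: Sequence[int],
    seed: int,
    gap: int = 0,
    skip_initial_met: bool = False,
) -> List[FPPPResult]:
    """Recompute the 190 c190 values on disjoint subsets of each given size.

    For each size the mean per pair is the arithmetic mean over subsets in
    which the pair is defined (divisor reduced otherwise); the standard
    error is the n-1 sample standard deviation over sqrt(number of defined
    subsets), reported as 0 when only one subset contributes.
    """
    if not subset_sizes:
        raise ValueError("subset_sizes must be non-empty")
    n = len(seqs)
    for size in subset_sizes:
        if size < 1 or size > n:
            raise ValueError(f"subset size {size} invalid for a set of {n}")
    per_seq = pair_count_matrix(seqs, gap=gap, skip_initial_met=skip_initial_met)
    results = []
    for size in subset_sizes:
        perm = np.random.default_rng(seed).permutation(n)
        c = _subset_c190_matrix(per_seq, perm, size)  # (k, 190)
        n_defined = np.sum(~np.isnan(c), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(
                n_defined > 0, np.nansum(c, axis=0) / np.maximum(n_defined, 1), np.nan
            )
            sd = np.full(c.shape[1], np.nan)
            multi = n_defined > 1
            # column-wise n-1 SD over defined subsets only
            for col in np.nonzero(multi)[0]:
                vals = c[:, col]
                vals = vals[~np.isnan(vals)]
                sd[col] = vals.std(ddof=1)
        se = np.where(n_defined > 1, sd / np.sqrt(n_defined), 0.0)
        se = np.where(n_defined == 0, np.nan, se)
        mean = np.where(n_defined == 0, np.nan, mean)
        per_pair = pd.DataFrame(
            {"mean_c190": mean, "std_error": se, "n_defined": n_defined},
            index=PAIR_LABELS,
        )
        results.append(
            FPPPResult(
                subset_size=size,
                n_subsets=len(c),
                per_pair=per_pair,
                seed=seed,
            )
        )
    return results


def fppp_report(
    results: Sequence[FPPPResult],
    full_c190: Optional[np.ndarray] = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Table-5-style report: one "mean(SE)" column per subset size, plus "all".

    ``full_c190`` is the 190-vector of full-set values (aligned with
    :data:`PAIR_LABELS`) for the final column, if available.
    """
    frame = pd.DataFrame(index=PAIR_LABELS)
    for res in results:
        col = [
            f"{m:.{decimals}f}({s:.{decimals}f})" if np.isfinite(m) else "undefined"
            for m, s in zip(res.per_pair["mean_c190"], res.per_pair["std_error"])
        ]
        frame[str(res.subset_size)] = col
    if full_c190 is not None:
        frame["all"] = [
            f"{v:.{decimals}f}" if np.isfinite(v) else "undefined" for v in full_c190
        ]
    frame.index.name = "pair"
    return frame


def bootstrap_c190(
    seqs: SequenceSet,
    n_boot: int = 200,
    seed: int = 0,
    gap: int = 0,
    skip_initial_met: bool = False,
) -> pd.DataFrame:
    """Sequence-level bootstrap of the 190 c190 values.

    Resamples whole sequences with replacement, recomputes c190 from the
    pooled counts of each resample, and reports the full-set point estimate
    with the bootstrap standard deviation as its standard error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    per_seq = pair_count_matrix(seqs, gap=gap, skip_initial_met=skip_initial_met)
    n = per_seq.shape[0]
    if n == 0:
        raise ValueError("cannot bootstrap an empty set")
    rng = np.random.default_rng(seed)
    point = pair_c190_vector(per_seq.sum(axis=0))
    boots = np.empty((n_boot, len(PAIR_LABELS)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = pair_c190_vector(per_seq[idx].sum(axis=0))
    with np.errstate(invalid="ignore"):
        se = np.nanstd(boots, axis=0, ddof=1)
    return pd.DataFrame(
        {"c190": point, "boot_se": se}, index=PAIR_LABELS
    )
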