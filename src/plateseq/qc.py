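"""Per-well QC summaries and gene-detection saturation curves.

Saturation is estimated by random subsampling of the read multiset implied
by each well's counts: drawing ``floor(fraction * total)`` reads without
replacement is a multivariate hypergeometric draw over genes, exactly
equivalent to uniform subsampling of the uniquely mapped reads given fixed
counts, and far cheaper than resampling FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .demux import CountMatrix

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


def _counts_frame(cm: Union[CountMatrix, pd.DataFrame]) -> pd.DataFrame:
    return cm.counts if isinstance(cm, CountMatrix) else cm


def genes_detected(
    cm: Union[CountMatrix, pd.DataFrame], min_count: int = 1
) -> pd.Series:
    """Number of genes with count >= ``min_count`` per well (spike-ins excluded)."""
    counts = _counts_frame(cm)
    return (counts >= min_count).sum(axis=0)


def subsample_counts(
    column: Union[pd.Series, np.ndarray],
    fraction: float,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> np.ndarray:
    """Subsample a count vector to a fraction of its reads, without replacement.

    Draws ``floor(fraction * total)`` reads from the multiset the counts
    describe (multivariate hypergeometric over genes); the returned vector
    sums to exactly that draw size. ``fraction == 1`` returns the input.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    col = np.asarray(column, dtype=np.int64)
    total = int(col.sum())
    if total == 0:
        return np.zeros_like(col)
    n = int(np.floor(fraction * total))
    if n == total:
        return col.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(col, n)


@dataclass
class SaturationCurve:
    """Mean genes detected (and s.e.m. across wells) per subsampling fraction."""

    fractions: np.ndarray
    mean_genes: np.ndarray
    sem_genes: np.ndarray
    n_reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_genes": self.mean_genes,
                "sem_genes": self.sem_genes,
            }
        )


def saturation_curve(
    cm: Union[CountMatrix, pd.DataFrame],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_reps: int = 10,
    seed: int = 0,
    min_count: int = 1,
) -> SaturationCurve:
    """Gene-detection saturation by random subsampling.

    For each fraction, each well is subsampled ``n_reps`` times and the
    per-well mean detection is averaged across wells; the error bar is the
    s.e.m. of the per-well means across wells. At fraction 1 the value
    equals the full-data detection exactly (no resampling noise).
    """
    counts = _counts_frame(cm)
    fracs = np.asarray(sorted(fractions), dtype=float)
    if ((fracs <= 0) | (fracs > 1)).any():
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_wells = counts.shape[1]
    means = np.empty(len(fracs))
    sems = np.empty(len(fracs))
    cols = [counts.iloc[:, j].to_numpy(dtype=np.int64) for j in range(n_wells)]
    for i, f in enumerate(fracs):
        well_means = np.empty(n_wells)
        for j, col in enumerate(cols):
            if f == 1.0:
                well_means[j] = int((col >= min_count).sum())
                continue
            det = [
                int((subsample_counts(col, f, rng) >= min_count).sum())
                for _ in range(n_reps)
            ]
            well_means[j] = float(np.mean(det))
        means[i] = well_means.mean()
        sems[i] = (
            well_means.std(ddof=1) / np.sqrt(n_wells) if n_wells > 1 else 0.0
        )
    return SaturationCurve(fracs, means, sems, n_reps)


def qc_table(cm: CountMatrix, min_count: int = 1) -> pd.DataFrame:
    """Per-well QC summary: read fates plus genes detected."""
    out = cm.stats.copy()
    out["genes_detected"] = genes_detected(cm, min_count=min_count)
    out["spikein_reads"] = cm.spike_counts.sum(axis=0).astype(int)
    return out
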