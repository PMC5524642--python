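"""Replicate noise: per-gene CV vs mean across duplicate pairs, and
perturbation-vs-vehicle fold-change distributions.

Given duplicate measurements of the same condition, the per-gene, per-pair
coefficient of variation (sample standard deviation over mean, so
``|x1 - x2| / (sqrt(2) * mean)`` for a pair) is averaged across all pairs
and plotted/tabulated against the average expression — the standard way to
compare platform noise floors across profiling technologies. Expression is
expected on a common linear scale (e.g. size-factor-normalized counts);
the module consumes generic replicate matrices, so cross-platform tables
can be fed in directly.
"""

from __future__ import annotations

from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .signatures import ExpressionMatrix


def per_pair_cv(x1: float, x2: float, ddof: int = 1) -> Tuple[float, float]:
    """Mean and CV of a duplicate pair.

    CV is the sample standard deviation (``ddof=1`` by default, i.e.
    ``|x1 - x2|/sqrt(2)``; ``ddof=0`` gives ``|x1 - x2|/2``) divided by the
    pair mean; undefined (NaN) when the mean is zero. Inputs must be
    non-negative linear-scale values.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("expression values must be non-negative")
    mean = (x1 + x2) / 2.0
    if mean == 0:
        return 0.0, float("nan")
    sd = abs(x1 - x2) / (np.sqrt(2.0) if ddof == 1 else 2.0)
    return mean, sd / mean


def duplicate_noise_table(
    expr: Union[ExpressionMatrix, pd.DataFrame],
    pairs: Sequence[Tuple[str, str]],
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-gene average expression and average CV across duplicate pairs.

    Pairs with zero mean for a gene contribute neither to that gene's CV
    average nor to its pair count (``n_pairs`` makes the exclusion
    auditable); the expression average runs over all pairs. Linear scale
    expected.
    """
    values = expr.linear() if isinstance(expr, ExpressionMatrix) else expr
    if not pairs:
        raise ValueError("at least one duplicate pair is required")
    for a, b in pairs:
        if a not in values.columns or b not in values.columns:
            raise ValueError(f"pair ({a!r}, {b!r}) references unknown columns")
    if (values.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")

    n_genes = values.shape[0]
    mean_sum = np.zeros(n_genes)
    cv_sum = np.zeros(n_genes)
    cv_n = np.zeros(n_genes, dtype=int)
    denom = np.sqrt(2.0) if ddof == 1 else 2.0
    for a, b in pairs:
        x1 = values[a].to_numpy(dtype=float)
        x2 = values[b].to_numpy(dtype=float)
        mean = (x1 + x2) / 2.0
        mean_sum += mean
        ok = mean > 0
        cv_sum[ok] += (np.abs(x1 - x2)[ok] / denom) / mean[ok]
        cv_n += ok
    with np.errstate(invalid="ignore"):
        mean_cv = np.where(cv_n > 0, cv_sum / np.maximum(cv_n, 1), np.nan)
    return pd.DataFrame(
        {
            "mean_expression": mean_sum / len(pairs),
            "mean_cv": mean_cv,
            "n_pairs": cv_n,
        },
        index=values.index,
    )


def fold_change_distribution(
    expr: Union[ExpressionMatrix, pd.DataFrame],
    controls: Union[Sequence[str], "object"],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold changes of every non-vehicle sample vs the
    vehicle-control mean: ``log2((x + pc) / (vehicle_mean + pc))``.

    ``controls`` is a list of vehicle sample labels or an object exposing
    ``vehicle_wells``. Linear-scale input; the pseudocount guards zeros.
    """
    values = expr.linear() if isinstance(expr, ExpressionMatrix) else expr
    control_samples = list(getattr(controls, "vehicle_wells", controls))
    if not control_samples:
        raise ValueError("at least one vehicle-control sample is required")
    missing = set(control_samples) - set(values.columns)
    if missing:
        raise ValueError(f"control samples absent from matrix: {sorted(missing)}")
    ref = values[control_samples].mean(axis=1)
    others = [c for c in values.columns if c not in control_samples]
    fc = np.log2(values[others].add(pseudocount, axis=0)).sub(
        np.log2(ref + pseudocount), axis=0
    )
    return fc


def fold_change_quantiles(
    fc: pd.DataFrame,
    quantiles: Sequence[float] = (0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99),
) -> pd.Series:
    """Summary quantiles of the pooled fold-change distribution."""
    flat = fc.to_numpy().ravel()
    flat = flat[np.isfinite(flat)]
    return pd.Series(np.quantile(flat, quantiles), index=list(quantiles))
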