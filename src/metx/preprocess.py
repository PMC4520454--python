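"""Value transformations applied before statistics.

Methylation beta values (fraction methylated, in [0, 1]) are mapped to
M-values, the logit2 transform ``M = log2(beta / (1 - beta))``, which is
unbounded and closer to homoscedastic, so downstream t-tests behave better
at the extremes of the methylation scale.  Expression intensities are
quantile normalized so every array shares one reference distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default clipping before the logit; array betas can be exactly 0 or 1
DEFAULT_EPSILON = 1e-6


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """Logit2 transform of beta values.

    Betas are clipped into ``[epsilon, 1 - epsilon]`` first so boundary
    values stay finite; interior values are essentially unmoved for the
    default ``epsilon = 1e-6``.  Accepts scalars, arrays, Series and
    DataFrames; NaN passes through.
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: ``beta = 2**M / (1 + 2**M)``, numerically stable for
    large |M|."""
    arr = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large positive M
    with np.errstate(over="ignore"):
        beta = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)),
                        2.0 ** arr / (1.0 + 2.0 ** arr))
    beta = np.where(np.isfinite(arr), beta, np.nan)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    if np.isscalar(m):
        return float(beta)
    return beta


def impute_row_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by the feature (row) median.

    Documented pre-step before :func:`quantile_normalize`, which requires a
    complete matrix.  Rows that are entirely missing raise.
    """
    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)][0]
        raise ValueError(f"feature {bad!r} has no observed values to impute from")
    med = matrix.median(axis=1)
    return matrix.apply(lambda col: col.fillna(med))


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across columns (samples).

    The reference distribution is the vector of row means of the
    column-sorted matrix.  Each column's values are replaced by the
    reference value at their within-column rank; tied values receive the
    mean of the reference values at the tied ranks, so within-column rank
    order is preserved and every column ends up with the identical sorted
    value vector (exactly so when there are no ties).
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix; "
                         "impute missing values first (impute_row_median)")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("quantile_normalize: non-finite values in matrix")
    n, p = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(p):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: average the reference values occupying the tied positions
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
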