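"""Quantile normalization against an averaged, optionally smoothed reference.

Every sample's empirical intensity distribution is forced onto a common
reference by rank substitution: the value at rank k in a sample is replaced
by the k-th entry of the reference quantile vector. The reference is the
mean of the samples' order statistics (the average sample distribution for
the data set).

In a cross-species experiment the reference is built from a relatively small
number of meaningful probesets over very few replicates, so it is noisy. To
stabilise it we smooth the averaged quantile vector with a seven-point
Savitzky-Golay filter — a sliding least-squares polynomial fit that
reproduces polynomials up to its fit order exactly. Smoothing can locally
break monotonicity of a quantile vector, which a distribution function must
have, so a pool-adjacent-violators isotonic repair is applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.signal import savgol_filter

from .errors import ParameterError
from .io import ExpressionMatrix

__all__ = [
    "ReferenceDistribution",
    "build_reference_distribution",
    "savitzky_golay_smooth",
    "quantile_normalize",
]


@dataclass(frozen=True)
class ReferenceDistribution:
    """Ordered quantile vector the samples are normalized onto.

    ``quantiles[k]`` is the target value for rank k; the vector is
    nondecreasing (isotonic repair is applied after smoothing) and its length
    equals the probe count of the matrix it was built from.
    """

    quantiles: np.ndarray
    smoothed: bool
    window: int

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles, dtype=float)
        object.__setattr__(self, "quantiles", q)
        if q.ndim != 1:
            raise ParameterError("reference quantiles must be a 1-D vector")
        if np.any(np.diff(q) < 0):
            raise ParameterError("reference quantiles must be nondecreasing")

    def __len__(self) -> int:
        return len(self.quantiles)


def savitzky_golay_smooth(v, window: int = 7, order: int = 2) -> np.ndarray:
    """Savitzky-Golay polynomial smoothing of a 1-D vector.

    Interior points get the classical convolution weights (for window 7,
    order 2: (-2, 3, 6, 7, 6, 3, -2)/21). The first and last (window-1)/2
    points are taken from the least-squares polynomial fitted to the first
    (last) ``window`` points, evaluated at their off-center positions, so no
    values are fabricated beyond the observed range.

    Parameters
    ----------
    v : array-like
        Input vector, length >= window.
    window : int
        Odd window length, >= 3.
    order : int
        Polynomial order of the fit, < window.
    """
    v = np.asarray(v, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if order < 0 or order >= window:
        raise ParameterError(f"order must satisfy 0 <= order < window, got {order}")
    if v.ndim != 1 or len(v) < window:
        raise ParameterError(f"need a 1-D vector of at least {window} points")
    return savgol_filter(v, window_length=window, polyorder=order, mode="interp")


def build_reference_distribution(
    m: ExpressionMatrix, smooth: bool = True, window: int = 7, order: int = 2
) -> ReferenceDistribution:
    """Average the samples' order statistics into a reference quantile vector.

    ``quantiles[k]`` is the mean over samples of each sample's k-th smallest
    intensity. With ``smooth=True`` the averaged vector is Savitzky-Golay
    filtered and then isotonic-repaired (pool-adjacent-violators), since
    smoothing can locally violate the monotonicity a distribution function
    requires.

    The matrix should already be presence-filtered so every sample
    contributes the same effective number of informative values.
    """
    if m.n_samples < 2:
        raise ParameterError("need at least 2 samples to build a reference")
    sorted_cols = np.sort(m.intensities.to_numpy(), axis=0)
    quantiles = sorted_cols.mean(axis=1)
    if smooth:
        if len(quantiles) < window:
            raise ParameterError(
                f"{len(quantiles)} probes is fewer than the smoothing window {window}"
            )
        quantiles = savitzky_golay_smooth(quantiles, window=window, order=order)
        quantiles = isotonic_regression(quantiles).x
    return ReferenceDistribution(quantiles=quantiles, smoothed=smooth, window=window)


def _normalize_column(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rank-substitute one sample's values with the reference quantiles.

    Ties receive the mean of the reference values at their tied ranks
    (deterministic and symmetric).
    """
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    n = len(values)
    # tie-group boundaries in the sorted vector
    starts = np.flatnonzero(np.concatenate(([True], sorted_vals[1:] != sorted_vals[:-1])))
    counts = np.diff(np.append(starts, n))
    group_means = np.add.reduceat(ref, starts) / counts
    out_sorted = np.repeat(group_means, counts)
    out = np.empty(n, dtype=float)
    out[order] = out_sorted
    return out


def quantile_normalize(m: ExpressionMatrix, ref: ReferenceDistribution) -> ExpressionMatrix:
    """Map every sample onto the reference distribution by rank substitution.

    After normalization the multiset of each sample's values equals
    ``ref.quantiles`` (up to tie-averaging); probe and sample order, presence
    flags and group labels are unchanged.
    """
    if len(ref) != m.n_probes:
        raise ParameterError(
            f"reference length {len(ref)} does not match probe count {m.n_probes}"
        )
    data = m.intensities.to_numpy()
    out = np.column_stack(
        [_normalize_column(data[:, j], ref.quantiles) for j in range(data.shape[1])]
    )
    normalized = pd.DataFrame(out, index=m.intensities.index, columns=m.intensities.columns)
    return ExpressionMatrix(
        intensities=normalized, present=m.present.copy(), groups=m.groups.copy()
    )
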