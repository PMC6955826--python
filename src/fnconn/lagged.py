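"""Distance correlation with circular-shift lags and surrogate significance.

Distance correlation (dCor) measures statistical dependence between two
random variables: it is zero only under independence and is sensitive to
nonlinear association.  The estimator used here is the original biased
V-statistic: pairwise absolute-difference matrices are double-centered
(row means, column means and the grand mean removed) and

    dCov^2(x, y) = mean(A ∘ B),      dVar^2(x) = mean(A ∘ A),
    dCor(x, y)   = dCov / sqrt(dVar_x * dVar_y)     in [0, 1].

Inter-network coupling in resting-state fMRI may be delayed by a few
samples, so the connectivity entry is the maximum of dCor over circular
shifts of one series within a small lag window.  Because dCor is positive
for any finite sample, edge existence is decided against a surrogate null
built from large circular rotations of one series, which preserve its
autocorrelation while destroying cross-dependence.

Implementation note: circularly rotating ``y`` by ``k`` samples permutes
its distance matrix by the same rotation on rows and columns, and double
centering commutes with simultaneous row/column permutation.  Hence
dCov^2 between ``x`` and every rotation of ``y`` is the diagonal of a 2-D
circular cross-correlation of the two centered matrices, computed in one
FFT.  Observed per-lag values use exact direct products; the FFT path
serves the surrogate null, where thousands of rotations are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, InvalidArgumentError

__all__ = [
    "DependencyResult",
    "distance_correlation",
    "lagged_distance_correlation",
    "surrogate_threshold",
    "surrogate_pvalue",
]


@dataclass
class DependencyResult:
    """Lag-maximized dependency between two series.

    ``dcor`` is the maximum of ``per_lag_values`` (ordered over lags
    ``-max_lag .. +max_lag``), attained at ``best_lag``.  A positive lag
    means the second series trails the first.  ``surrogate_p`` is filled
    when a surrogate test was run.
    """

    dcor: float
    best_lag: int
    per_lag_values: np.ndarray
    surrogate_p: float | None = None

    @property
    def max_lag(self) -> int:
        return (len(self.per_lag_values) - 1) // 2


def _as_series(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise InvalidArgumentError(f"{name} must have length >= 4, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError(f"{name} contains non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError(f"{name} is constant; dCor is undefined")
    return x


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered pairwise absolute-difference matrix."""
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


class _PreparedSeries:
    """Centered distance matrix of one series plus its cached spectrum.

    Reused across the many pairs/rotations of a connectivity matrix so the
    O(n^2) centering and the FFT are paid once per node.
    """

    def __init__(self, x: np.ndarray):
        self.x = np.ascontiguousarray(_as_series(x, "series"))
        self.n = self.x.size
        self.A = _centered_distances(self.x)
        self.dvar2 = float(np.vdot(self.A, self.A)) / self.n**2  # V^2(x) >= 0
        self._spectrum: np.ndarray | None = None

    @property
    def spectrum(self) -> np.ndarray:
        """Row-wise real FFT of the centered matrix in diagonal coordinates
        (row d = the cyclic diagonal i - j = d), cached."""
        if self._spectrum is None:
            n = self.n
            t = np.arange(n)
            diag = self.A[(t[None, :] + t[:, None]) % n, t[None, :]]
            self._spectrum = np.fft.rfft(diag, axis=1)
        return self._spectrum


def _rotation_dcov2_profile(px: _PreparedSeries, py: _PreparedSeries) -> np.ndarray:
    """dCov^2(x, rot_k(y)) for every rotation k = 0..n-1 via FFT.

    rot_k(y)[t] = y[(t - k) mod n]; its centered matrix is the centered
    matrix of y with rows and columns rotated by k (double centering
    commutes with a simultaneous row/column permutation), so

        dCov^2(k) = (1/n^2) sum_ij A[i+k, j+k] B[i, j].

    Simultaneous rotation preserves cyclic diagonals, so this is a sum of
    n one-dimensional circular cross-correlations, one per diagonal,
    evaluated together in the frequency domain.
    """
    n = px.n
    s = (px.spectrum * np.conj(py.spectrum)).sum(axis=0)
    return np.fft.irfft(s, n=n) / (n * n)


def _dcor_from_dcov2(dcov2: np.ndarray | float, dvar2_x: float, dvar2_y: float):
    denom = np.sqrt(dvar2_x * dvar2_y)
    if denom == 0:
        raise DegenerateSeriesError("zero distance variance; dCor is undefined")
    return np.sqrt(np.clip(np.asarray(dcov2, dtype=float), 0.0, None) / denom).clip(0.0, 1.0)


def distance_correlation(x, y) -> float:
    """Distance correlation (biased V-statistic) between two equal-length series.

    Returns a value in [0, 1]; 0 is approached only under independence and
    1 is attained for exact (even nonlinear monotone-affine) dependence of
    one variable on the other.

    Raises
    ------
    InvalidArgumentError
        If lengths differ or a series is shorter than 4 samples.
    DegenerateSeriesError
        If either series is constant.
    """
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if x.size != y.size:
        raise InvalidArgumentError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    A = _centered_distances(x)
    B = _centered_distances(y)
    dcov2 = float(np.vdot(A, B)) / (n * n)
    dvx = float(np.vdot(A, A)) / (n * n)
    dvy = float(np.vdot(B, B)) / (n * n)
    return float(_dcor_from_dcov2(dcov2, dvx, dvy))


def _lag_preference_order(max_lag: int):
    """Candidate lags ordered by the tie-break rule: smaller |lag| first,
    negative before positive at equal magnitude."""
    yield 0
    for m in range(1, max_lag + 1):
        yield -m
        yield m


def _lagged_from_prepared(
    px: _PreparedSeries, py: _PreparedSeries, max_lag: int
) -> DependencyResult:
    n = px.n
    lags = np.arange(-max_lag, max_lag + 1)
    dcov2 = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag == 0:
            dcov2[i] = float(np.vdot(px.A, py.A)) / (n * n)
        else:
            # shift y by -lag: rot_{-lag}(y) permutes y's centered matrix
            rot = np.roll(py.A, (-lag, -lag), axis=(0, 1))
            dcov2[i] = float(np.vdot(px.A, rot)) / (n * n)
    values = np.asarray(_dcor_from_dcov2(dcov2, px.dvar2, py.dvar2))
    best_lag = 0
    best = -np.inf
    for lag in _lag_preference_order(max_lag):
        v = values[lag + max_lag]
        if v > best:
            best, best_lag = float(v), int(lag)
    return DependencyResult(dcor=best, best_lag=best_lag, per_lag_values=values)


def lagged_distance_correlation(x, y, max_lag: int) -> DependencyResult:
    """Maximum distance correlation over circular shifts of ``y``.

    Evaluates ``distance_correlation(x, circular_shift(y, lag))`` for every
    integer lag in ``[-max_lag, max_lag]`` (a positive lag realigns a ``y``
    that trails ``x``) and returns the maximum with its lag.  Ties are
    broken toward smaller ``|lag|``, then toward the negative lag.
    """
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if x.size != y.size:
        raise InvalidArgumentError(f"length mismatch: {x.size} vs {y.size}")
    if max_lag < 0:
        raise InvalidArgumentError("max_lag must be >= 0")
    if max_lag >= x.size / 4:
        raise InvalidArgumentError("max_lag must be below n/4")
    return _lagged_from_prepared(_PreparedSeries(x), _PreparedSeries(y), max_lag)


def _surrogate_null(
    px: _PreparedSeries,
    py: _PreparedSeries,
    max_lag: int,
    n_surrogates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null sample of the lag-maximized dCor under random large rotations of y.

    Rotations are drawn uniformly from ``[max_lag + 1, n - max_lag - 1]`` so
    no surrogate overlaps the observed lag window at either wrap-around end.
    A rotation followed by a lag shift is itself a rotation, so every null
    value is a window maximum over the precomputed rotation profile.
    """
    n = px.n
    lo, hi = max_lag + 1, n - max_lag - 1
    if lo > hi:
        raise InvalidArgumentError("series too short for the requested lag window")
    profile = _rotation_dcov2_profile(px, py)
    rotations = rng.integers(lo, hi + 1, size=n_surrogates)
    # lagged stat of (x, rot_r(y)) maximizes dCov^2 at rotations r - lag
    offsets = np.arange(-max_lag, max_lag + 1)
    windows = profile[(rotations[:, None] - offsets[None, :]) % n]
    null_dcov2 = windows.max(axis=1)
    return np.asarray(_dcor_from_dcov2(null_dcov2, px.dvar2, py.dvar2))


def surrogate_threshold(
    x, y, max_lag: int, n_surrogates: int = 100, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical ``1 - alpha`` quantile of the lag-maximized dCor null.

    The null is built from ``n_surrogates`` random circular rotations of
    ``y`` (each at least ``max_lag + 1`` samples), which preserve the
    marginal autocorrelation of both series while breaking any cross
    dependence.  An observed statistic above the threshold is retained as
    an edge at level ``alpha``.
    """
    if not 0 < alpha <= 1:
        raise InvalidArgumentError("alpha must be in (0, 1]")
    if n_surrogates < 20:
        raise InvalidArgumentError("n_surrogates must be >= 20")
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if x.size != y.size:
        raise InvalidArgumentError(f"length mismatch: {x.size} vs {y.size}")
    null = _surrogate_null(
        _PreparedSeries(x), _PreparedSeries(y), max_lag, n_surrogates,
        np.random.default_rng(seed),
    )
    # "higher" keeps the threshold an order statistic of the null sample
    # (alpha = 1 returns the null minimum).
    return float(np.quantile(null, 1.0 - alpha, method="higher"))


def surrogate_pvalue(null: np.ndarray, observed: float) -> float:
    """Permutation-style p-value ``(1 + #{null >= observed}) / (1 + n)``."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))
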