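"""Four-Gaussian decomposition of image intensity histograms.

Each grayscale image is summarized by its 256-bin intensity histogram,
which is then modeled as a sum of four Gaussian functions

    g(b) = sum_j a_j * exp(-(b - m_j)^2 / (2 s_j^2)),   j = 1..4

fitted by seeded multi-start nonlinear least squares over the bins.  The
per-image feature vector is a fixed-length-4 projection of the fitted
parameters — by default the four component means, sorted ascending, which
track where the intensity mass of background, tissue and (hypoechoic)
lesion sits.  All twelve raw parameters remain accessible on the model.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

N_COMPONENTS = 4
N_BINS = 256

_SIGMA_MIN, _SIGMA_MAX = 0.5, 255.0


@dataclasses.dataclass
class Histogram:
    """Normalized 256-bin intensity histogram (bin centers 0..255)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        total = self.counts.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"histogram must be normalized to sum 1, sums to {total}")

    @property
    def bins(self) -> np.ndarray:
        return np.arange(N_BINS, dtype=float)


@dataclasses.dataclass
class HistogramModel:
    """Fitted four-Gaussian histogram model.

    ``components`` is a (4, 3) array of rows (amplitude, mean, sigma),
    sorted by ascending mean; ``residual`` is the sum of squared errors of
    the fit over the 256 bins; ``converged`` records optimizer success.
    """

    components: np.ndarray
    residual: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (N_COMPONENTS, 3):
            raise ValueError(f"expected {(N_COMPONENTS, 3)} components array")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")
        order = np.argsort(self.components[:, 1], kind="stable")
        self.components = self.components[order]

    @property
    def amplitudes(self) -> np.ndarray:
        return self.components[:, 0]

    @property
    def means(self) -> np.ndarray:
        return self.components[:, 1]

    @property
    def widths(self) -> np.ndarray:
        return self.components[:, 2]


def gaussian_mixture_curve(params: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Evaluate sum_j a_j exp(-(b-m_j)^2 / (2 s_j^2)) on the given bins."""
    p = np.asarray(params, dtype=float).reshape(-1, 3)
    a, m, s = p[:, 0:1], p[:, 1:2], p[:, 2:3]
    return np.sum(a * np.exp(-((bins[None, :] - m) ** 2) / (2.0 * s ** 2)), axis=0)


def compute_histogram(img: np.ndarray, mask: np.ndarray | None = None) -> Histogram:
    """256-bin normalized intensity histogram of an image (or a region)."""
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    values = arr[np.asarray(mask, dtype=bool)] if mask is not None else arr.ravel()
    if values.size == 0:
        raise ValueError("empty region")
    if values.min() < 0 or values.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    counts = np.bincount(values.astype(np.int64), minlength=N_BINS).astype(float)
    return Histogram(counts / counts.sum())


def _weighted_quantile_positions(hist: Histogram, qs: Sequence[float]) -> np.ndarray:
    cdf = np.cumsum(hist.counts)
    return np.array([np.searchsorted(cdf, q) for q in qs], dtype=float)


def _initial_guesses(hist: Histogram, seed: int, n_restarts: int) -> list[np.ndarray]:
    """Quartile-anchored start plus seeded perturbations."""
    centers = _weighted_quantile_positions(hist, (0.125, 0.375, 0.625, 0.875))
    amp = np.maximum(hist.counts[centers.astype(int)], 1e-4)
    base = np.column_stack([amp, centers, np.full(N_COMPONENTS, 12.0)])
    guesses = [base]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts - 1):
        jitter = base.copy()
        jitter[:, 1] = np.clip(base[:, 1] + rng.normal(0, 20, N_COMPONENTS), 0, 255)
        jitter[:, 2] = np.clip(base[:, 2] * rng.uniform(0.3, 3.0, N_COMPONENTS),
                               _SIGMA_MIN, _SIGMA_MAX)
        jitter[:, 0] = base[:, 0] * rng.uniform(0.5, 2.0, N_COMPONENTS)
        guesses.append(jitter)
    return guesses


def fit_gaussian_curve(counts: np.ndarray, seed: int = 0,
                       n_restarts: int = 5) -> HistogramModel:
    """Least-squares four-Gaussian fit to an arbitrary 256-bin count vector.

    The workhorse behind :func:`fit_four_gaussians`; accepting unnormalized
    counts makes the fit's scale equivariance (counts scaled by c -> only
    amplitudes scaled by c) directly testable.
    """
    target = np.asarray(counts, dtype=float)
    if target.shape != (N_BINS,) or np.any(target < 0):
        raise ValueError(f"counts must be {N_BINS} non-negative values")
    total = target.sum()
    if total <= 0:
        raise ValueError("counts must not be all zero")
    bins = np.arange(N_BINS, dtype=float)
    norm_hist = Histogram(target / total)  # initialization anchors only

    def resid(flat: np.ndarray) -> np.ndarray:
        return gaussian_mixture_curve(flat, bins) - target

    lower = np.tile([0.0, 0.0, _SIGMA_MIN], N_COMPONENTS)
    upper = np.tile([np.inf, 255.0, _SIGMA_MAX], N_COMPONENTS)

    best: tuple[float, np.ndarray, bool] | None = None
    for guess in _initial_guesses(norm_hist, seed, n_restarts):
        guess = guess.copy()
        guess[:, 0] *= total  # amplitude starts on the counts' scale
        x0 = np.clip(guess.ravel(), lower, upper)
        try:
            sol = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                                max_nfev=2000)
        except Exception:  # numerical failure on this start only
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol.x, bool(sol.success))
    if best is None:
        raise RuntimeError("four-Gaussian fit failed on every start")
    sse, params, ok = best
    return HistogramModel(params.reshape(N_COMPONENTS, 3), residual=sse, converged=ok)


def fit_four_gaussians(hist: Histogram, seed: int = 0,
                       n_restarts: int = 5) -> HistogramModel:
    """Fit the four-Gaussian model to a histogram by multi-start least squares.

    Bound constraints: a_j >= 0, m_j in [0, 255], s_j in [0.5, 255].  The
    first start anchors component means at the quartile positions of the
    histogram mass; further starts are seeded perturbations, so the fit is
    deterministic given ``seed``.  If no start converges, the best-so-far
    parameters are returned with ``converged=False``.
    """
    return fit_gaussian_curve(hist.counts, seed=seed, n_restarts=n_restarts)


_SCHEMES: dict[str, Callable[[HistogramModel], np.ndarray]] = {
    "means": lambda m: m.means,
    "amplitudes": lambda m: m.amplitudes,
    "widths": lambda m: m.widths,
}


def extract_features(model: HistogramModel,
                     scheme: str | Callable[[HistogramModel], np.ndarray] = "means"
                     ) -> np.ndarray:
    """Project a fitted model onto a fixed-length-4 feature vector.

    ``scheme`` is one of ``means`` (default), ``amplitudes``, ``widths``, or
    a callable mapping the model to 4 values.
    """
    selector = _SCHEMES.get(scheme, scheme) if isinstance(scheme, str) else scheme
    if isinstance(selector, str):
        raise ValueError(f"unknown feature scheme {scheme!r}; "
                         f"choose from {sorted(_SCHEMES)} or pass a callable")
    values = np.asarray(selector(model), dtype=float)
    if values.shape != (N_COMPONENTS,):
        raise ValueError(f"feature scheme must yield {N_COMPONENTS} values, "
                         f"got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("features must be finite")
    return values
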