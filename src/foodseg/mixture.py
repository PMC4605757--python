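"""1-D Gaussian mixture fitting with MML model selection and thresholding.

The grey-level histogram of the selected difference image is modeled as a
mixture of at most two Gaussians,

    f(y | Theta) = sum_m pi_m N(y; mu_m, sigma_m^2),

fitted by Expectation-Maximization on a weighted (binned) histogram.  The
number of components (one vs. two) is chosen by the minimum-message-length
(MML) criterion: the candidate minimizing

    ML = (N_p/2) * sum_m ln(n*pi_m/12) + (C/2) * ln(n/12)
         + C*(N_p+1)/2 - loglik

with N_p = 2 free parameters per 1-D Gaussian component.  Two components
give a Bayes-rule threshold (the weighted-density crossover between the
means); a single component gives a tail-rejection threshold at mu +/- k*sigma
on the side of the heavier tail (sample skewness decides the side).

All fits are deterministic: EM is initialized at evenly spaced quantiles of
the data with equal weights and the data variance, never at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FitConfig",
    "Mixture1D",
    "ThresholdDecision",
    "fit_em",
    "message_length",
    "select_model",
    "bayes_threshold",
    "kurtosis_threshold",
]

_N_PARAMS_PER_COMPONENT = 2  # mean and variance of a 1-D Gaussian
_LOG_FLOOR = 1e-300


@dataclass
class FitConfig:
    """Tunables of the mixture stage; none of them is data-dependent."""

    c_max: int = 2
    em_tol: float = 1e-7        # relative log-likelihood change to stop
    max_iter: int = 500
    variance_floor: float = 1e-4  # fraction of the data variance
    n_bins: int = 256
    seed: int = 0
    kurtosis_k: float = 2.0     # tail cutoff multiplier, threshold = mu +/- k*sigma

    def __post_init__(self) -> None:
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")
        for name in ("em_tol", "max_iter", "variance_floor", "n_bins", "kurtosis_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Mixture1D:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    C: int
    loglik: float
    n: float
    converged: bool
    message_length: float = np.nan
    degenerate: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = np.zeros_like(x, dtype=np.float64)
        for w, mu, var in zip(self.weights, self.means, self.variances):
            out += w * np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
        return out

    def as_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "C": self.C,
            "loglik": self.loglik,
            "message_length": float(self.message_length),
            "n": self.n,
            "converged": self.converged,
        }


@dataclass
class ThresholdDecision:
    """An intensity cutoff plus which side of it is foreground."""

    threshold: float
    method: str                  # "bayes" | "kurtosis"
    C_selected: int
    foreground_side: str         # "above" | "below"
    mixture: Mixture1D

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "method": self.method,
            "C_selected": self.C_selected,
            "foreground_side": self.foreground_side,
            "mixture": self.mixture.as_dict(),
        }


def _as_histogram(
    values, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Accept raw samples or a (centers, counts) pair; return (centers, counts)."""
    if isinstance(values, tuple) and len(values) == 2:
        centers = np.asarray(values[0], dtype=np.float64)
        counts = np.asarray(values[1], dtype=np.float64)
        if centers.shape != counts.shape:
            raise ValueError("bin centers and counts must have equal length")
        return centers, counts
    v = np.asarray(values, dtype=np.float64).ravel()
    if not np.isfinite(v).all():
        raise ValueError("non-finite intensities")
    if v.size and v.min() == v.max():
        # constant data: numpy would pad the range and shift the bin center
        return np.array([v[0]]), np.array([float(v.size)])
    counts, edges = np.histogram(v, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return centers[keep], counts[keep].astype(np.float64)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(q, cum, x)


def fit_em(values, C: int, config: FitConfig | None = None) -> Mixture1D:
    """Fit a C-component 1-D Gaussian mixture by EM on a weighted histogram.

    ``values`` may be a raw intensity sample (binned to ``config.n_bins``
    equal-width bins first) or an explicit ``(bin_centers, bin_counts)``
    pair.  The log-likelihood is nondecreasing across iterations; the fit is
    deterministic (quantile initialization).  Data with zero variance yields
    a flagged single-component fit at the variance floor.
    """
    config = config or FitConfig()
    if C < 1:
        raise ValueError("C must be >= 1")
    x, w = _as_histogram(values, config.n_bins)
    n = float(w.sum())
    if n < 10 * C:
        raise ValueError(f"need at least {10 * C} observations for C={C}, got {n:g}")

    mean_all = float(np.average(x, weights=w))
    var_all = float(np.average((x - mean_all) ** 2, weights=w))
    if var_all == 0.0:
        mix = Mixture1D(
            weights=np.array([1.0]),
            means=np.array([mean_all]),
            variances=np.array([max(1e-12, abs(mean_all) * 1e-12)]),
            C=1, loglik=0.0, n=n, converged=True, degenerate=True,
        )
        mix.message_length = message_length(mix)
        return mix

    floor = config.variance_floor * var_all
    q = (np.arange(C) + 0.5) / C
    means = _weighted_quantile(x, w, q)
    variances = np.full(C, var_all)
    weights = np.full(C, 1.0 / C)

    loglik = -np.inf
    converged = False
    trace: list[float] = []
    for _ in range(config.max_iter):
        # E-step: responsibilities of each component for each bin
        dens = np.empty((x.size, C))
        for m in range(C):
            dens[:, m] = weights[m] * np.exp(
                -0.5 * (x - means[m]) ** 2 / variances[m]
            ) / np.sqrt(2 * np.pi * variances[m])
        total = dens.sum(axis=1)
        new_loglik = float(np.dot(w, np.log(np.maximum(total, _LOG_FLOOR))))
        trace.append(new_loglik)
        resp = dens / np.maximum(total, _LOG_FLOOR)[:, None]

        # M-step on bin weights
        nk = resp.T @ w
        weights = nk / n
        safe_nk = np.maximum(nk, _LOG_FLOOR)
        means = (resp * w[:, None]).T @ x / safe_nk
        for m in range(C):
            variances[m] = max(
                float(np.dot(resp[:, m] * w, (x - means[m]) ** 2) / safe_nk[m]),
                floor,
            )

        if np.isfinite(loglik) and abs(new_loglik - loglik) <= config.em_tol * abs(
            loglik if loglik != 0 else 1.0
        ):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    order = np.argsort(means)
    mix = Mixture1D(
        weights=weights[order], means=means[order], variances=variances[order],
        C=C, loglik=loglik, n=n, converged=converged,
        loglik_trace=np.asarray(trace),
    )
    mix.message_length = message_length(mix)
    return mix


def message_length(model: Mixture1D) -> float:
    """MML score of a fitted mixture; lower is better.

    Zero-weight components carry no message and are excluded; C counts the
    surviving components only.
    """
    live = model.weights > 0
    c_live = int(live.sum())
    np_ = _N_PARAMS_PER_COMPONENT
    return float(
        (np_ / 2.0) * np.sum(np.log(model.n * model.weights[live] / 12.0))
        + (c_live / 2.0) * np.log(model.n / 12.0)
        + c_live * (np_ + 1) / 2.0
        - model.loglik
    )


def select_model(values, config: FitConfig | None = None) -> Mixture1D:
    """Fit C = 1 .. c_max and return the message-length minimizer."""
    config = config or FitConfig()
    best: Mixture1D | None = None
    for c in range(1, config.c_max + 1):
        mix = fit_em(values, c, config)
        if best is None or mix.message_length < best.message_length:
            best = mix
        if mix.degenerate:
            break  # zero-variance data: larger C cannot help
    assert best is not None
    return best


def bayes_threshold(model: Mixture1D) -> ThresholdDecision:
    """Decision boundary of a two-component mixture under the Bayes rule.

    The threshold t solves pi_1 N(t; mu_1, s1) = pi_2 N(t; mu_2, s2) inside
    [mu_1, mu_2], so that thresholding at t reproduces the MAP classification
    there.  The quadratic is solved in closed form; if no root lies between
    the means (extreme weight/variance imbalance) a dense posterior-crossover
    grid search over [mu_1, mu_2] is used instead.  ``foreground_side``
    defaults to "above"; the segmentation stage may override it from image
    geometry.
    """
    if model.C != 2:
        raise ValueError("bayes_threshold requires a 2-component mixture")
    (m1, m2) = model.means
    (v1, v2) = model.variances
    (p1, p2) = model.weights
    if m1 == m2:
        raise ValueError("components not separated")

    # log p1 N1(t) = log p2 N2(t)  ->  a t^2 + b t + c = 0
    a = 0.5 / v2 - 0.5 / v1
    b = m1 / v1 - m2 / v2
    c = m2**2 / (2 * v2) - m1**2 / (2 * v1) + np.log((p1 * np.sqrt(v2)) / (p2 * np.sqrt(v1)))

    roots: list[float] = []
    if abs(a) < 1e-300:
        if b != 0:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [t for t in roots if m1 <= t <= m2]

    if inside:
        t = float(inside[0]) if len(inside) == 1 else float(min(inside, key=lambda r: abs(r - (m1 + m2) / 2)))
    else:
        grid = np.linspace(m1, m2, 1_000_001)
        d1 = p1 * np.exp(-0.5 * (grid - m1) ** 2 / v1) / np.sqrt(2 * np.pi * v1)
        d2 = p2 * np.exp(-0.5 * (grid - m2) ** 2 / v2) / np.sqrt(2 * np.pi * v2)
        t = float(grid[np.argmin(np.abs(d1 - d2))])

    return ThresholdDecision(
        threshold=t, method="bayes", C_selected=2, foreground_side="above",
        mixture=model,
    )


def kurtosis_threshold(
    values, model: Mixture1D, config: FitConfig | None = None
) -> ThresholdDecision:
    """Tail-rejection threshold for a unimodal fit.

    The heavier tail is identified by the sample skewness of ``values``:
    positive skewness rejects the upper tail (threshold mu + k*sigma,
    foreground below), negative rejects the lower tail (mu - k*sigma,
    foreground above).  Zero skewness rejects nothing (threshold +inf,
    foreground below).
    """
    config = config or FitConfig()
    if model.C != 1:
        raise ValueError("kurtosis_threshold requires a 1-component fit")
    v = np.asarray(values, dtype=np.float64).ravel()
    skew = float(stats.skew(v))
    mu = float(model.means[0])
    sigma = float(np.sqrt(model.variances[0]))
    k = config.kurtosis_k
    if skew > 1e-8:
        t, side = mu + k * sigma, "below"
    elif skew < -1e-8:
        t, side = mu - k * sigma, "above"
    else:
        t, side = np.inf, "below"
    return ThresholdDecision(
        threshold=float(t), method="kurtosis", C_selected=1,
        foreground_side=side, mixture=model,
    )
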