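"""Poisson GLM of CA1 activity on thalamic firing over non-REM sleep.

Spike/event times are binned through the rest periods (250 ms bins tiled from
each interval start, trailing partial bins dropped) and CA1 counts are
regressed on thalamic counts with a log link::

    log(mu) = beta0 + beta1 * X        mu = exp(beta0 + beta1 * X)

Maximum likelihood is by iteratively reweighted least squares; beta1's
significance uses the Wald test (normal approximation).  The fitted
coefficient translates into an interpretable rate change:
``100 * (exp(beta1 * delta_x) - 1)`` percent per ``delta_x`` predictor units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .state import StateIntervals


@dataclass
class CountSeries:
    bin_starts: np.ndarray       # seconds, each bin is [start, start + bin_s)
    counts: np.ndarray           # non-negative integers
    bin_s: float
    source: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def rate(self) -> np.ndarray:
        """Counts converted to events/s."""
        return self.counts / self.bin_s


@dataclass
class GlmFit:
    beta0: float
    beta1: float
    se0: float
    se1: float
    wald_p: float
    mu_hat: np.ndarray = field(repr=False)
    converged: bool = True


def bin_counts(times: np.ndarray, rest: StateIntervals,
               bin_s: float = 0.25, source: str = "") -> CountSeries:
    """Tile each rest interval with ``bin_s`` bins from its start (trailing
    partial bins dropped) and count events by half-open membership."""
    times = np.asarray(times, dtype=float)
    starts_all = []
    counts_all = []
    for s, e in rest.rest:
        n = int(np.floor((e - s) / bin_s))
        if n == 0:
            continue
        edges = s + bin_s * np.arange(n + 1)
        c = np.searchsorted(times, edges[1:]) - np.searchsorted(times, edges[:-1])
        starts_all.append(edges[:-1])
        counts_all.append(c)
    if not starts_all:
        import warnings
        warnings.warn("rest intervals shorter than one bin: empty count series")
        return CountSeries(np.empty(0), np.empty(0, dtype=int), bin_s, source)
    return CountSeries(np.concatenate(starts_all),
                       np.concatenate(counts_all).astype(int), bin_s, source)


def fit_poisson_glm(y: CountSeries | np.ndarray,
                    x: CountSeries | np.ndarray) -> GlmFit:
    """Fit ``y ~ Poisson(exp(beta0 + beta1 x))`` by IRLS.

    Convergence at max |delta beta| < 1e-8 or 100 iterations; standard errors
    from the observed information; Wald p for beta1 from the normal
    approximation.  Raises on a constant predictor (degenerate design).
    """
    yv = y.counts if isinstance(y, CountSeries) else np.asarray(y, dtype=float)
    xv = x.counts if isinstance(x, CountSeries) else np.asarray(x, dtype=float)
    if len(yv) != len(xv):
        raise ValueError("y and x must have aligned bins")
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor: beta1 unidentifiable")
    X = sm.add_constant(np.asarray(xv, dtype=float))
    model = sm.GLM(np.asarray(yv, dtype=float), X,
                   family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    beta0, beta1 = res.params
    se0, se1 = res.bse
    return GlmFit(beta0=float(beta0), beta1=float(beta1), se0=float(se0),
                  se1=float(se1), wald_p=float(res.pvalues[1]),
                  mu_hat=np.asarray(res.mu), converged=bool(res.converged))


def rate_change_percent(fit: GlmFit, delta_x: float) -> float:
    """Percent change in the response rate per ``delta_x`` predictor units:
    ``100 (exp(beta1 delta_x) - 1)`` (negative delta_x models a drop)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return float(100.0 * (np.exp(fit.beta1 * delta_x) - 1.0))
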