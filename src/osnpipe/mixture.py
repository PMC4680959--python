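"""Two-component Gaussian mixture deconvolution of OR abundance.

Olfactory receptor expression events, on the log10 normalized-count
scale, form a bimodal distribution: a low-abundance background class and
a high-abundance monogenic class.  A two-component Gaussian mixture is
fitted by expectation-maximization, and the crossing point of the two
weighted component densities between the means — the intersection
threshold tau, returned on the normalized-count scale — separates
"abundant" from background expression.

The model is exposed statsmodels-style: :class:`AbundanceMixture` is
built from the data, ``fit()`` returns an
:class:`AbundanceMixtureResults` carrying parameter estimates,
diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import ConfigurationError, FitError


@dataclass
class EMConfig:
    """EM controls: iteration cap, log-likelihood tolerance, restarts, seed."""

    max_iter: int = 5000
    tol: float = 1e-8
    n_restarts: int = 5
    seed: int = 0
    min_sigma: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")


class AbundanceMixture:
    """Two-component 1-D Gaussian mixture model of log10 expression.

    Parameters
    ----------
    log_counts
        1-D array of log10(normalized counts) for expression events
        (zero-count events are not events and must not be included).
    """

    def __init__(self, log_counts) -> None:
        x = np.asarray(log_counts, dtype=float).ravel()
        if x.size < 2 or np.unique(x).size < 2:
            raise ConfigurationError(
                "mixture fit requires at least 2 distinct values"
            )
        if not np.isfinite(x).all():
            raise ConfigurationError("log counts must be finite")
        self.endog = x

    # -- EM internals ------------------------------------------------
    def _loglik(self, w, mu, sigma) -> float:
        dens = w[0] * norm.pdf(self.endog, mu[0], sigma[0]) + w[1] * norm.pdf(
            self.endog, mu[1], sigma[1]
        )
        return float(np.log(np.maximum(dens, 1e-300)).sum())

    def _run_em(self, mu0, sigma0, w0, config: EMConfig):
        x = self.endog
        w, mu, sigma = np.array(w0, float), np.array(mu0, float), np.array(sigma0, float)
        ll_old = self._loglik(w, mu, sigma)
        trace = [ll_old]
        converged = False
        for _ in range(config.max_iter):
            # E step
            p0 = w[0] * norm.pdf(x, mu[0], sigma[0])
            p1 = w[1] * norm.pdf(x, mu[1], sigma[1])
            total = np.maximum(p0 + p1, 1e-300)
            r1 = p1 / total
            r0 = 1.0 - r1
            # M step
            n0, n1 = r0.sum(), r1.sum()
            if n0 < 2 or n1 < 2:
                raise FitError("component collapsed onto fewer than 2 events")
            w = np.array([n0, n1]) / x.size
            mu = np.array([(r0 * x).sum() / n0, (r1 * x).sum() / n1])
            var = np.array(
                [(r0 * (x - mu[0]) ** 2).sum() / n0, (r1 * (x - mu[1]) ** 2).sum() / n1]
            )
            sigma = np.sqrt(np.maximum(var, config.min_sigma**2))
            ll = self._loglik(w, mu, sigma)
            if ll < ll_old - 1e-8 * (1.0 + abs(ll_old)):
                raise FitError("EM log-likelihood decreased — degenerate fit")
            trace.append(ll)
            if ll - ll_old < config.tol:
                converged = True
                ll_old = ll
                break
            ll_old = ll
        return w, mu, sigma, ll_old, converged, trace

    def fit(self, config: EMConfig | None = None) -> "AbundanceMixtureResults":
        """Maximize the two-component likelihood by EM with restarts.

        Initialization splits the data at the empirical median; further
        restarts jitter the split point.  The best (highest
        log-likelihood) non-degenerate restart is kept; components are
        ordered so mu1 < mu2.
        """
        config = config or EMConfig()
        x = self.endog
        rng = np.random.default_rng(config.seed)
        best = None
        errors: list[str] = []
        for r in range(config.n_restarts):
            split = np.median(x)
            if r > 0:
                split += rng.normal(0.0, 0.25 * (x.std() + 1e-12))
            lo, hi = x[x <= split], x[x > split]
            if lo.size < 1 or hi.size < 1:
                lo, hi = x[: x.size // 2], x[x.size // 2 :]
            s_all = max(x.std(), config.min_sigma)
            mu0 = (lo.mean(), hi.mean() if hi.size else lo.mean() + s_all)
            sigma0 = (
                max(lo.std(), 0.25 * s_all, config.min_sigma),
                max(hi.std() if hi.size else s_all, 0.25 * s_all, config.min_sigma),
            )
            w0 = (max(lo.size, 1) / x.size, max(hi.size, 1) / x.size)
            try:
                w, mu, sigma, ll, conv, trace = self._run_em(mu0, sigma0, w0, config)
            except FitError as exc:
                errors.append(str(exc))
                continue
            if best is None or ll > best[3]:
                best = (w, mu, sigma, ll, conv, trace)
        if best is None:
            raise FitError(
                "all EM restarts degenerate: " + "; ".join(errors[:3])
            )
        w, mu, sigma, ll, conv, trace = best
        order = np.argsort(mu)
        return AbundanceMixtureResults(
            model=self,
            weights=w[order],
            means=mu[order],
            sigmas=sigma[order],
            loglik=ll,
            converged=conv,
            n_events=x.size,
            loglik_trace=np.array(trace),
        )


@dataclass
class AbundanceMixtureResults:
    """Fitted two-component mixture: parameters, diagnostics, threshold."""

    model: AbundanceMixture
    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    loglik: float
    converged: bool
    n_events: int
    loglik_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def separation(self) -> float:
        """Component separation |mu2 - mu1| / pooled sigma; < 2 suggests
        the data are effectively unimodal and the threshold unreliable."""
        pooled = np.sqrt(
            self.weights[0] * self.sigmas[0] ** 2 + self.weights[1] * self.sigmas[1] ** 2
        )
        return float(abs(self.means[1] - self.means[0]) / max(pooled, 1e-300))

    def log10_intersection(self) -> float:
        """Crossing point of the weighted component densities between the
        means, on the log10 scale (quadratic in x; the in-between root)."""
        (w1, w2), (m1, m2), (s1, s2) = self.weights, self.means, self.sigmas
        if np.isclose(s1, s2):
            # equal variances: linear equation, closed form
            x = 0.5 * (m1 + m2) + s1**2 * np.log(w1 / w2) / (m2 - m1)
            if not (m1 < x < m2):
                raise FitError(
                    "no density intersection between the component means; "
                    "set a manual threshold"
                )
            return float(x)
        a = 1.0 / s1**2 - 1.0 / s2**2
        b = -2.0 * (m1 / s1**2 - m2 / s2**2)
        c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * np.log((w1 * s2) / (w2 * s1))
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise FitError(
                "no real density intersection (pathological overlap); "
                "set a manual threshold"
            )
        roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
        between = [r for r in roots if m1 < r < m2]
        if not between:
            raise FitError(
                "no density intersection between the component means; "
                "set a manual threshold"
            )
        return float(between[0])

    def intersection(self) -> float:
        """Threshold tau on the normalized-count scale (10**log10 root)."""
        return float(10.0 ** self.log10_intersection())

    def intersection_bisect(self, xtol: float = 1e-12) -> float:
        """Numeric cross-check: bisection root of the density difference
        between the means, on the log10 scale."""
        (w1, w2), (m1, m2), (s1, s2) = self.weights, self.means, self.sigmas

        def diff(x):
            return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

        return float(brentq(diff, m1 + 1e-12, m2 - 1e-12, xtol=xtol))

    def summary(self) -> str:
        lines = [
            "Two-component Gaussian mixture (log10 normalized counts)",
            f"  n events:       {self.n_events}",
            f"  converged:      {self.converged}",
            f"  log-likelihood: {self.loglik:.4f}",
            f"  component 1:    w={self.weights[0]:.3f}  mu={self.means[0]:.3f}  sigma={self.sigmas[0]:.3f}",
            f"  component 2:    w={self.weights[1]:.3f}  mu={self.means[1]:.3f}  sigma={self.sigmas[1]:.3f}",
            f"  separation:     {self.separation:.2f}",
        ]
        try:
            tau = self.intersection()
            lines.append(f"  intersection:   {tau:.1f} normalized counts")
        except FitError as exc:
            lines.append(f"  intersection:   unavailable ({exc})")
        return "\n".join(lines)


def fit_mixture(log_counts, config: EMConfig | None = None) -> AbundanceMixtureResults:
    """Convenience wrapper: build and fit an :class:`AbundanceMixture`."""
    return AbundanceMixture(log_counts).fit(config)


def mixture_intersection(fit: AbundanceMixtureResults) -> float:
    """Threshold tau (normalized-count scale) for a converged fit."""
    return fit.intersection()
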