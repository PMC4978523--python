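"""Cumulative-Gaussian psychometric fitting for 2AFC numerosity comparison.

The choice law is P(right judged more numerous) = Φ((x − μ)/σ), with x the
numerosity difference normalized by the mean of the two stimuli.  μ is the
point of subjective equality (PSE): the physical difference at which the
two sides appear equally numerous.  A rightward shift of the curve
(positive μ) means the right-side stimulus is underestimated.

Fitting maximizes the trial-wise Bernoulli likelihood with a multi-start
bounded quasi-Newton optimizer seeded from a coarse grid; σ is bounded
below at 1e-4 to exclude degenerate step functions.  No lapse-rate
parameter is fitted (curves run 0 → 1); the machinery accepts one as an
extension point but it is off by default.

:class:`PsychometricModel` / :class:`PsychometricResults` follow the
model-object convention: build from data, ``fit()``, read estimates,
standard errors and ``summary()`` off the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .exceptions import DegenerateDataError, InvalidParameterError

__all__ = [
    "PsychometricFit",
    "FCAdaptationResult",
    "PsychometricModel",
    "PsychometricResults",
    "normalized_difference",
    "fit_psychometric",
    "pse",
    "adaptation_magnitude_2afc",
    "bin_proportions",
]

_SIGMA_FLOOR = 1e-4


def normalized_difference(n_right, n_left):
    """x = (n_right − n_left) / ((n_right + n_left)/2); accepts arrays."""
    nr = np.asarray(n_right, dtype=float)
    nl = np.asarray(n_left, dtype=float)
    if np.any(nr < 1) or np.any(nl < 1):
        raise InvalidParameterError("numerosities must be >= 1")
    x = (nr - nl) / ((nr + nl) / 2.0)
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted cumulative-Gaussian parameters with diagnostics."""

    mu: float
    sigma: float
    log_likelihood: float
    n_trials: int
    converged: bool
    mu_se: float = float("nan")
    sigma_se: float = float("nan")


@dataclass(frozen=True)
class FCAdaptationResult:
    """PSE per adaptation level and the fast−slow magnitude in percent."""

    pse_fast: float
    pse_slow: float
    magnitude_percent: float
    pse_baseline: float | None = None


def _aggregate(x: np.ndarray, choices: np.ndarray):
    """Collapse trials onto unique x levels: (levels, n_right, n_total)."""
    levels, inv = np.unique(x, return_inverse=True)
    k = np.bincount(inv, weights=choices.astype(float))
    m = np.bincount(inv).astype(float)
    return levels, k, m


def _neg_loglik(params, levels, k, m):
    mu, sigma = params
    z = (levels - mu) / sigma
    return -(np.sum(k * norm.logcdf(z)) + np.sum((m - k) * norm.logsf(z)))


class PsychometricModel:
    """Bernoulli cumulative-Gaussian model of one set of 2AFC choices."""

    def __init__(self, x, choices):
        x = np.asarray(x, dtype=float)
        choices = np.asarray(choices).astype(bool)
        if x.shape != choices.shape or x.ndim != 1:
            raise InvalidParameterError("x and choices must be equal-length 1-D")
        if len(np.unique(x)) < 2:
            raise DegenerateDataError("need >= 2 distinct stimulus levels")
        if choices.all() or (~choices).all():
            raise DegenerateDataError(
                "all choices identical: the MLE is not finite"
            )
        self.x = x
        self.choices = choices
        self._levels, self._k, self._m = _aggregate(x, choices)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "PsychometricModel":
        """Build from a 2AFC trial table (columns x, choice_right_more)."""
        return cls(trials["x"].to_numpy(), trials["choice_right_more"].to_numpy())

    def loglike(self, mu: float, sigma: float) -> float:
        return -_neg_loglik((mu, sigma), self._levels, self._k, self._m)

    def fit(self, n_starts: int = 4) -> "PsychometricResults":
        lv = self._levels
        span = max(lv.max() - lv.min(), 1e-3)
        bounds = [(lv.min() - span, lv.max() + span), (_SIGMA_FLOOR, 10.0 * span)]
        # coarse grid supplies the starting points
        mu0 = np.linspace(lv.min(), lv.max(), 9)
        sg0 = np.geomspace(span / 50, span, 7)
        grid = [(m, s) for m in mu0 for s in sg0]
        scores = [_neg_loglik(p, lv, self._k, self._m) for p in grid]
        starts = [grid[i] for i in np.argsort(scores)[:n_starts]]
        best = None
        for p0 in starts:
            res = optimize.minimize(
                _neg_loglik, p0, args=(lv, self._k, self._m),
                method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        mu, sigma = best.x
        mu_se, sigma_se = self._standard_errors(mu, sigma)
        fit = PsychometricFit(
            mu=float(mu), sigma=float(sigma),
            log_likelihood=float(-best.fun),
            n_trials=int(self._m.sum()),
            converged=bool(best.success),
            mu_se=mu_se, sigma_se=sigma_se,
        )
        return PsychometricResults(self, fit)

    def _standard_errors(self, mu, sigma):
        """SEs from the observed information (finite-difference Hessian)."""
        h = np.array([1e-5, 1e-5])
        p = np.array([mu, sigma])
        H = np.empty((2, 2))
        f0 = _neg_loglik(p, self._levels, self._k, self._m)
        for i in range(2):
            for j in range(2):
                pp = p.copy(); pp[i] += h[i]; pp[j] += h[j]
                pm = p.copy(); pm[i] += h[i]; pm[j] -= h[j]
                mp = p.copy(); mp[i] -= h[i]; mp[j] += h[j]
                mm = p.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                H[i, j] = (
                    _neg_loglik(pp, self._levels, self._k, self._m)
                    - _neg_loglik(pm, self._levels, self._k, self._m)
                    - _neg_loglik(mp, self._levels, self._k, self._m)
                    + _neg_loglik(mm, self._levels, self._k, self._m)
                ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            return float(se[0]), float(se[1])
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")


class PsychometricResults:
    """Results wrapper: estimates, SEs, predictions and a summary table."""

    def __init__(self, model: PsychometricModel, fit: PsychometricFit):
        self.model = model
        self.fit_result = fit

    @property
    def mu(self) -> float:
        return self.fit_result.mu

    @property
    def sigma(self) -> float:
        return self.fit_result.sigma

    @property
    def llf(self) -> float:
        return self.fit_result.log_likelihood

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def predict(self, x) -> np.ndarray:
        """P(right judged more numerous) at stimulus level(s) x."""
        return norm.cdf((np.asarray(x, dtype=float) - self.mu) / self.sigma)

    def pse_percent(self) -> float:
        return pse(self.fit_result)

    def summary(self) -> str:
        f = self.fit_result
        return "\n".join([
            "Cumulative-Gaussian psychometric fit (MLE)",
            "=" * 44,
            f"n trials        {f.n_trials}",
            f"mu (PSE)        {f.mu: .5f}  (SE {f.mu_se:.5f})  = {100*f.mu:.2f}%",
            f"sigma           {f.sigma: .5f}  (SE {f.sigma_se:.5f})",
            f"log-likelihood  {f.log_likelihood: .3f}",
            f"converged       {f.converged}",
        ])

    def __repr__(self):
        return (f"<PsychometricResults mu={self.mu:.4f} "
                f"sigma={self.sigma:.4f} n={self.fit_result.n_trials}>")


def fit_psychometric(x, choices) -> PsychometricFit:
    """Functional wrapper: MLE fit returning the bare :class:`PsychometricFit`."""
    return PsychometricModel(x, choices).fit().fit_result


def pse(fit: PsychometricFit) -> float:
    """PSE in percent units of the normalized-difference axis (100·μ)."""
    if not fit.converged:
        raise DegenerateDataError(
            "fit did not converge; refusing to report a PSE "
            f"(loglik={fit.log_likelihood}, n={fit.n_trials})"
        )
    return 100.0 * fit.mu


def adaptation_magnitude_2afc(
    fit_fast: PsychometricFit,
    fit_slow: PsychometricFit,
    fit_baseline: PsychometricFit | None = None,
) -> FCAdaptationResult:
    """Adaptation magnitude: PSE(fast) − PSE(slow), in percent.

    Positive when fast tapping shifts the curve rightward, i.e. the adapted
    (right) side is underestimated after fast tapping relative to slow.
    """
    p_fast = pse(fit_fast)
    p_slow = pse(fit_slow)
    p_base = pse(fit_baseline) if fit_baseline is not None else None
    return FCAdaptationResult(
        pse_fast=p_fast, pse_slow=p_slow,
        magnitude_percent=p_fast - p_slow, pse_baseline=p_base,
    )


def bin_proportions(
    trials: pd.DataFrame, n_bins: int = 9, equal_count: bool = True
) -> pd.DataFrame:
    """Binned choice proportions for plotting (fits always use raw trials).

    Returns columns x_bin_center, proportion_right, n.  ``equal_count``
    selects quantile bins; otherwise bins are equal-width in x.
    """
    if trials is None or len(trials) == 0:
        raise InvalidParameterError("empty trial table")
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    x = trials["x"].to_numpy(dtype=float)
    c = trials["choice_right_more"].to_numpy(dtype=float)
    if equal_count:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        rows.append({
            "x_bin_center": float(x[mask].mean()),
            "proportion_right": float(c[mask].mean()),
            "n": int(mask.sum()),
        })
    return pd.DataFrame(rows)
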