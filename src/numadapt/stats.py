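"""Statistical toolkit: repeated-measures ANOVA, t-tests, effect sizes, power.

The pieces are the ones an estimation/discrimination psychophysics study
needs:

* a 2×K repeated-measures ANOVA (adaptation level × numerosity, both
  within-subject) with F, p, and η² in both the classical
  (SS_effect/SS_total) and partial (SS_effect/(SS_effect+SS_error))
  variants;
* a one-way ANOVA for comparing adaptation magnitudes across conditions;
* a two-tailed paired t-test with Cohen's d;
* the η² → Cohen's d conversion d = 2·sqrt(η²/(1−η²)) and its inverse;
* one-sample t power and minimum sample size via the noncentral t.

Tail probabilities come from the regularized incomplete beta function; a
numerical-integration oracle in the test suite pins them to 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import nct
from scipy.stats import t as t_dist

from .exceptions import DegenerateDataError, InvalidParameterError, MissingCellError

__all__ = [
    "AnovaResult",
    "TTestResult",
    "PowerSpec",
    "eta_sq_to_cohens_d",
    "cohens_d_to_eta_sq",
    "t_tail_probability",
    "paired_t_test",
    "one_way_anova",
    "rm_anova_2xK",
    "power_at",
    "required_sample_size",
]


@dataclass(frozen=True)
class AnovaResult:
    effect_name: str
    F: float
    df1: int
    df2: int
    p: float
    eta_sq: float           # classical: SS_effect / SS_total
    eta_sq_partial: float   # SS_effect / (SS_effect + SS_error)
    cohens_d: float         # from the classical eta_sq

    def __str__(self):
        return (f"{self.effect_name}: F({self.df1},{self.df2}) = {self.F:.3f}, "
                f"p = {self.p:.4g}, eta^2 = {self.eta_sq:.4f} "
                f"(partial {self.eta_sq_partial:.4f}), d = {self.cohens_d:.3f}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float

    def __str__(self):
        return (f"t({self.df}) = {self.t:.3f}, p = {self.p:.4g}, "
                f"d = {self.cohens_d:.3f}")


@dataclass(frozen=True)
class PowerSpec:
    alpha: float
    power: float
    effect_size_d: float
    n: int
    tails: str = "two"


def eta_sq_to_cohens_d(eta_sq: float) -> float:
    """Cohen's d from η²: d = 2·sqrt(η² / (1 − η²))."""
    if not 0.0 <= eta_sq < 1.0:
        raise InvalidParameterError("eta_sq must lie in [0, 1)")
    return 2.0 * math.sqrt(eta_sq / (1.0 - eta_sq))


def cohens_d_to_eta_sq(d: float) -> float:
    """Inverse conversion: η² = d² / (d² + 4)."""
    return d * d / (d * d + 4.0)


def t_tail_probability(t: float, df: float, tails: str = "two") -> float:
    """Tail mass of Student's t beyond |t|, via the incomplete beta function.

    One-tailed gives P(T ≥ |t|); two-tailed doubles it.
    """
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    if tails not in ("one", "two"):
        raise InvalidParameterError("tails must be 'one' or 'two'")
    x = df / (df + t * t)
    one_tail = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return float(min(1.0, (2.0 if tails == "two" else 1.0) * one_tail))


def paired_t_test(a, b) -> TTestResult:
    """Two-tailed paired t-test; Cohen's d = mean(a−b)/SD(a−b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidParameterError("a and b must be equal-length 1-D with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    return TTestResult(
        t=float(t), df=n - 1,
        p=t_tail_probability(t, n - 1, "two"),
        cohens_d=float(d.mean() / sd),
    )


def one_way_anova(groups) -> AnovaResult:
    """Between-groups one-way ANOVA with η² = SS_between / SS_total."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InvalidParameterError("need >= 2 groups with >= 2 observations each")
    all_obs = np.concatenate(arrays)
    grand = all_obs.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = all_obs.size - len(arrays)
    if ss_within == 0 and ss_between == 0:
        raise DegenerateDataError("all observations identical")
    ms_within = ss_within / df2
    if ms_within == 0:
        raise DegenerateDataError("zero within-group variance")
    F = (ss_between / df1) / ms_within
    ss_total = ss_between + ss_within
    eta = ss_between / ss_total
    return AnovaResult(
        effect_name="group", F=float(F), df1=df1, df2=df2,
        p=_f_tail(F, df1, df2),
        eta_sq=float(eta), eta_sq_partial=float(eta),
        cohens_d=eta_sq_to_cohens_d(min(eta, 1 - 1e-15)),
    )


def _f_tail(F: float, df1: int, df2: int) -> float:
    """Upper tail of the F distribution via the incomplete beta function."""
    if F <= 0:
        return 1.0
    x = df2 / (df2 + df1 * F)
    return float(special.betainc(df2 / 2.0, df1 / 2.0, x))


def rm_anova_2xK(
    table: pd.DataFrame,
    subject: str = "subject_id",
    factor_a: str = "adaptation",
    factor_b: str = "n_true",
    dv: str = "response",
) -> list[AnovaResult]:
    """Two-way fully-within repeated-measures ANOVA on cell means.

    The table is first reduced to one mean per subject × A × B cell (the
    conventional RM reduction of trial-level data); the design must then be
    complete.  Sums of squares are partitioned into subject, A, B, A×B and
    their subject-interaction error terms; each effect is tested against
    its own effect-by-subject error (F = MS_effect / MS_effect×subject).
    No sphericity correction is applied.
    """
    cells = (
        table.groupby([subject, factor_a, factor_b], sort=True)[dv]
        .mean().reset_index()
    )
    pivot = cells.pivot_table(
        index=subject, columns=[factor_a, factor_b], values=dv
    )
    if pivot.isna().any().any():
        bad = [
            {subject: s, factor_a: a, factor_b: b}
            for s in pivot.index
            for (a, b) in pivot.columns[pivot.loc[s].isna()]
        ]
        raise MissingCellError(bad)
    a_levels = sorted(cells[factor_a].unique())
    b_levels = sorted(cells[factor_b].unique())
    ns, na, nb = len(pivot), len(a_levels), len(b_levels)
    if ns < 2:
        raise InvalidParameterError("need >= 2 subjects")
    Y = pivot.to_numpy().reshape(ns, na, nb)

    g = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_s = na * nb * np.sum((m_s - g) ** 2)
    ss_a = ns * nb * np.sum((m_a - g) ** 2)
    ss_b = ns * na * np.sum((m_b - g) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = nb * np.sum((m_as - m_a[None, :] - m_s[:, None] + g) ** 2)
    ss_bs = na * np.sum((m_bs - m_b[None, :] - m_s[:, None] + g) ** 2)
    ss_total = np.sum((Y - g) ** 2)
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    effects = [
        (factor_a, ss_a, na - 1, ss_as, (na - 1) * (ns - 1)),
        (factor_b, ss_b, nb - 1, ss_bs, (nb - 1) * (ns - 1)),
        (f"{factor_a}*{factor_b}", ss_ab, (na - 1) * (nb - 1),
         ss_abs, (na - 1) * (nb - 1) * (ns - 1)),
    ]
    results = []
    for name, ss_eff, df1, ss_err, df2 in effects:
        ms_err = ss_err / df2
        if ms_err == 0:
            if ss_eff > 1e-12:
                raise DegenerateDataError(f"zero error variance for effect {name!r}")
            F = 0.0  # no effect and no error variance: flat data
        else:
            F = (ss_eff / df1) / ms_err
        eta = ss_eff / ss_total if ss_total > 0 else 0.0
        eta_p = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        results.append(AnovaResult(
            effect_name=name, F=float(F), df1=df1, df2=df2,
            p=_f_tail(F, df1, df2),
            eta_sq=float(eta), eta_sq_partial=float(eta_p),
            cohens_d=eta_sq_to_cohens_d(min(eta, 1 - 1e-15)),
        ))
    return results


def power_at(n: int, effect_size_d: float, alpha: float = 0.05,
             tails: str = "two") -> float:
    """Power of the one-sample t-test at size n under noncentrality d·√n."""
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if tails not in ("one", "two"):
        raise InvalidParameterError("tails must be 'one' or 'two'")
    df = n - 1
    ncp = effect_size_d * math.sqrt(n)
    if tails == "two":
        crit = t_dist.ppf(1 - alpha / 2, df)
        return float(nct.sf(crit, df, ncp) + nct.cdf(-crit, df, ncp))
    crit = t_dist.ppf(1 - alpha, df)
    return float(nct.sf(crit, df, ncp))


def required_sample_size(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.8,
    tails: str = "two", n_max: int = 1_000_000,
) -> PowerSpec:
    """Smallest n whose one-sample t-test reaches the target power."""
    if effect_size_d == 0:
        raise InvalidParameterError("power target unreachable at d = 0")
    if not 0 < power < 1:
        raise InvalidParameterError("power must lie in (0, 1)")
    d = abs(effect_size_d)
    for n in range(2, n_max + 1):
        if power_at(n, d, alpha, tails) >= power:
            return PowerSpec(alpha=alpha, power=power,
                             effect_size_d=effect_size_d, n=n, tails=tails)
    raise InvalidParameterError(f"power {power} not reached by n = {n_max}")
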