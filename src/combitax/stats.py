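"""Primitive hypothesis tests of the interplay framework.

Three building blocks, all operating on a :class:`~combitax.model.ModeratedFit`:

* one-sided tests of linear contrasts of the four condition means (is an
  intervention effective? is the interaction positive/negative?);
* TOST equivalence tests establishing that a contrast lies inside a symmetric
  tolerance interval ``[-eps, eps]`` (is an intervention inert? is the
  combined effect approximately the sum of the single effects?);
* intersection-union compounding: a conjunction of partial alternatives is
  accepted iff every partial test rejects at level alpha, so the compound
  p-value is the maximum of the partial p-values and the compound test is
  level alpha whenever each partial is.

All statistics use the moderated standard error ``s~_g * sqrt(sum w_c^2/n_c)``
and the moderated degrees of freedom; infinite df falls back to the standard
normal (the Student-t limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from scipy import stats as sps

from .model import ModeratedFit

__all__ = [
    "Contrast", "TestResult", "TostSpec", "TostResult",
    "A_VS_C", "B_VS_C", "AB_VS_C", "INTERACTION",
    "contrast_estimates", "contrast_pvalues", "contrast_test",
    "tost_pvalues", "tost", "compound_iut", "t_critical",
]


@dataclass(frozen=True)
class Contrast:
    """A linear contrast of the four condition means, e.g. A-C or the
    interaction AB-A-B+C.  Weights must sum to zero."""

    weights: Mapping[str, float]
    label: str

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total) > 1e-12:
            raise ValueError(f"contrast weights must sum to 0, got {total}")
        if sum(1 for w in self.weights.values() if w != 0) < 2:
            raise ValueError("a contrast needs at least two nonzero weights")


#: Effect of A alone.
A_VS_C = Contrast({"A": 1.0, "C": -1.0}, "A-C")
#: Effect of B alone.
B_VS_C = Contrast({"B": 1.0, "C": -1.0}, "B-C")
#: Effect of the combination.
AB_VS_C = Contrast({"AB": 1.0, "C": -1.0}, "AB-C")
#: Combined effect minus the sum of single effects.
INTERACTION = Contrast({"AB": 1.0, "A": -1.0, "B": -1.0, "C": 1.0}, "interaction")


@dataclass
class TestResult:
    """Outcome of a one-sided contrast test for one feature."""

    estimate: float
    se: float
    statistic: float
    df: float
    p: float
    direction: str
    degenerate: bool = False


@dataclass(frozen=True)
class TostSpec:
    """Symmetric equivalence interval [-eps, eps] on the log2 scale."""

    eps: float

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ValueError(f"tolerance eps must be positive, got {self.eps}")


@dataclass
class TostResult:
    """Outcome of a two-one-sided-tests equivalence test for one feature.

    Near-equality is accepted iff both statistics exceed the critical value
    ``t_{df,1-alpha}``, equivalently iff ``p = max(p_lower, p_upper) < alpha``.
    """

    estimate: float
    se: float
    u_upper: float
    u_lower: float
    p_upper: float
    p_lower: float
    p: float
    df: float
    critical: float
    accepted: bool
    degenerate: bool = False


def _upper_tail(t: np.ndarray, df: float) -> np.ndarray:
    """P(T_df > t); standard normal when df is infinite."""
    if math.isinf(df):
        return sps.norm.sf(t)
    return sps.t.sf(t, df)


def t_critical(df: float, alpha: float) -> float:
    """Upper critical value t_{df,1-alpha} (normal quantile for infinite df)."""
    if math.isinf(df):
        return float(sps.norm.ppf(1.0 - alpha))
    return float(sps.t.ppf(1.0 - alpha, df))


def contrast_estimates(fit: ModeratedFit, c: Contrast):
    """Vectorised estimate and moderated SE of a contrast for every feature.

    Returns ``(psi_hat, se)`` arrays aligned with ``fit.feature_ids``.
    """
    est = np.zeros(len(fit.means))
    leverage = 0.0
    for cond, w in c.weights.items():
        if w == 0:
            continue
        est += w * fit.means[cond].to_numpy()
        leverage += w * w / fit.replicate_counts[cond]
    se = np.sqrt(fit.s2_tilde.to_numpy() * leverage)
    return est, se


def contrast_pvalues(fit: ModeratedFit, c: Contrast, direction: str) -> np.ndarray:
    """Vectorised one-sided p-values for a contrast (NaN for degenerate
    features, which have no standard error)."""
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    est, se = contrast_estimates(fit, c)
    degen = fit.degenerate.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.nan)
    if direction == "less":
        t = -t
    p = _upper_tail(t, fit.df_tilde)
    p = np.where(degen, np.nan, p)
    return p


def contrast_test(fit: ModeratedFit, feature, c: Contrast,
                  direction: str = "greater") -> TestResult:
    """One-sided moderated t-test of a single contrast for one feature."""
    idx = fit.means.index.get_loc(feature)
    est, se = contrast_estimates(fit, c)
    est, se = float(est[idx]), float(se[idx])
    degen = bool(fit.degenerate.iloc[idx])
    if degen or se == 0.0:
        return TestResult(estimate=est, se=se, statistic=math.nan,
                          df=fit.df_tilde, p=math.nan, direction=direction,
                          degenerate=True)
    t = est / se
    signed = -t if direction == "less" else t
    p = float(_upper_tail(np.asarray(signed), fit.df_tilde))
    return TestResult(estimate=est, se=se, statistic=t, df=fit.df_tilde,
                      p=p, direction=direction)


def tost_pvalues(fit: ModeratedFit, c: Contrast, spec: TostSpec) -> np.ndarray:
    """Vectorised TOST p-values, max of the two one-sided p-values."""
    est, se = contrast_estimates(fit, c)
    degen = fit.degenerate.to_numpy()
    safe_se = np.where(se > 0, se, 1.0)
    u_upper = (spec.eps - est) / safe_se
    u_lower = (est + spec.eps) / safe_se
    p = np.maximum(_upper_tail(u_upper, fit.df_tilde),
                   _upper_tail(u_lower, fit.df_tilde))
    p = np.where(degen | (se == 0), np.nan, p)
    return p


def tost(fit: ModeratedFit, feature, c: Contrast, spec: TostSpec,
         alpha: float = 0.05) -> TostResult:
    """TOST equivalence test of a single contrast against [-eps, eps].

    Both one-sided statistics ``U_upper = (eps - psi_hat)/SE`` and
    ``U_lower = (psi_hat + eps)/SE`` must exceed ``t_{df,1-alpha}`` for
    near-equality to be accepted.
    """
    idx = fit.means.index.get_loc(feature)
    est_all, se_all = contrast_estimates(fit, c)
    est, se = float(est_all[idx]), float(se_all[idx])
    crit = t_critical(fit.df_tilde, alpha)
    degen = bool(fit.degenerate.iloc[idx])
    if degen or se == 0.0:
        return TostResult(estimate=est, se=se, u_upper=math.nan,
                          u_lower=math.nan, p_upper=math.nan, p_lower=math.nan,
                          p=math.nan, df=fit.df_tilde, critical=crit,
                          accepted=False, degenerate=True)
    u_upper = (spec.eps - est) / se
    u_lower = (est + spec.eps) / se
    p_upper = float(_upper_tail(np.asarray(u_upper), fit.df_tilde))
    p_lower = float(_upper_tail(np.asarray(u_lower), fit.df_tilde))
    p = max(p_upper, p_lower)
    return TostResult(estimate=est, se=se, u_upper=u_upper, u_lower=u_lower,
                      p_upper=p_upper, p_lower=p_lower, p=p, df=fit.df_tilde,
                      critical=crit, accepted=p < alpha)


def compound_iut(partials: Sequence[float], alpha: float):
    """Intersection-union compounding of partial p-values.

    The compound alternative (all partial alternatives hold simultaneously)
    is accepted iff every partial p-value is below alpha; the compound
    p-value is the maximum.  A NaN partial (degenerate feature) makes the
    compound undecidable and is treated as p = 1.
    """
    partials = list(partials)
    if not partials:
        raise ValueError("compound_iut requires at least one partial p-value")
    clean = [1.0 if (p is None or math.isnan(p)) else float(p) for p in partials]
    p_compound = max(clean)
    return p_compound < alpha, p_compound
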