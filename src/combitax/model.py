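"""Per-feature linear model for the 2x2 factorial design with empirical-Bayes
variance moderation.

The design crosses two interventions A and B, giving four conditions: an
untreated control ``C``, the single interventions ``A`` and ``B``, and the
combination ``AB``.  For every feature (probeset, gene, transcript) the model
is simply a cell-means one-way layout over the four conditions: each
condition mean is estimated by the arithmetic mean of its replicates and a
single pooled residual variance ``s_g^2`` with ``d_g = N - 4`` degrees of
freedom is computed per feature.

With only a handful of replicates per condition, the per-feature variance is
noisy.  It is stabilised by shrinking towards a common prior: assuming
``s_g^2`` follows a scaled inverse chi-square distribution with prior degrees
of freedom ``d0`` and prior variance ``s0^2``, the posterior (moderated)
variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and downstream t-statistics gain degrees of freedom, ``df~ = d0 + d_g``.
``(d0, s0^2)`` are estimated from the full set of per-feature variances by
moment matching on the log scale (the variance of ``log s_g^2`` in excess of
the known sampling component identifies ``d0`` through the trigamma
function).  ``d0 = +inf`` means no excess dispersion: every feature gets the
common variance ``s0^2`` and normal instead of t tails downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger("combitax")

#: Canonical condition labels of the 2x2 design, in display order.
CONDITIONS = ("C", "A", "B", "AB")

#: d0 values above this are reported as +inf (no measurable excess dispersion).
D0_CAP = 1e8

#: Absolute tolerance of the trigamma root-finder for d0.
D0_ROOT_TOL = 1e-8


class CombitaxError(Exception):
    """Base class for all package errors."""


class InputError(CombitaxError):
    """Malformed input data (bad file, duplicate ids, non-numeric cells)."""


class ConfigurationError(CombitaxError):
    """Invalid configuration or design (missing condition, bad alpha/eps)."""


class InsufficientReplicationError(ConfigurationError):
    """The design leaves no residual degrees of freedom."""


class EstimationError(CombitaxError):
    """Hyperparameter estimation is impossible (too few usable variances)."""


# ---------------------------------------------------------------------------
# Input containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features x samples log2 expression matrix.

    ``data`` is indexed by feature id with one column per sample.  Rows
    containing missing values are dropped at construction (their count is
    logged and kept in ``n_dropped``); duplicate feature or sample ids are
    rejected.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise InputError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise InputError(f"duplicate sample id: {dup!r}")
        non_numeric = [c for c in self.data.columns
                       if not np.issubdtype(self.data[c].dtype, np.number)]
        if non_numeric:
            raise InputError(f"non-numeric expression columns: {non_numeric}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build a matrix from a features x samples frame, dropping rows
        with missing values (the count is logged)."""
        complete = df.dropna(axis=0, how="any")
        n_dropped = len(df) - len(complete)
        if n_dropped:
            logger.warning("dropped %d feature(s) with missing values", n_dropped)
        return cls(data=complete.astype(float), n_dropped=n_dropped)

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]


@dataclass
class DesignMap:
    """Maps each sample id to one of the four conditions C/A/B/AB."""

    assignment: dict

    def __post_init__(self) -> None:
        bad = sorted({c for c in self.assignment.values() if c not in CONDITIONS})
        if bad:
            raise ConfigurationError(
                f"unknown condition label(s) {bad}; expected one of {CONDITIONS}")
        missing = [c for c in CONDITIONS if c not in set(self.assignment.values())]
        if missing:
            raise ConfigurationError(f"design is missing condition(s): {missing}")
        if self.residual_df < 1:
            raise InsufficientReplicationError(
                f"residual df = N - 4 = {self.residual_df}; need at least 1")
        if self.residual_df == 1:
            logger.warning("residual df is 1; variance estimates will be very "
                           "unstable (2 or more recommended)")

    @property
    def replicate_counts(self) -> dict:
        counts = {c: 0 for c in CONDITIONS}
        for cond in self.assignment.values():
            counts[cond] += 1
        return counts

    @property
    def n_total(self) -> int:
        return len(self.assignment)

    @property
    def residual_df(self) -> int:
        return self.n_total - len(CONDITIONS)

    def samples_for(self, condition: str) -> list:
        return [s for s, c in self.assignment.items() if c == condition]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Raw per-feature fit: condition means, pooled variance, residual df."""

    means: pd.DataFrame        # features x 4, columns = CONDITIONS
    s2: pd.Series              # pooled residual variance per feature
    d_g: int                   # residual degrees of freedom, N - 4

    @property
    def degenerate(self) -> pd.Series:
        """True for features whose replicates are all identical (s2 == 0);
        such features have no standard error and are never classified."""
        return self.s2 == 0.0


def fit_condition_means(matrix: ExpressionMatrix, design: DesignMap) -> FitResult:
    """Estimate condition means and the pooled residual variance per feature.

    The pooled variance is the within-condition sum of squares over all four
    conditions divided by ``N - 4``; unequal replicate counts are handled by
    the same formula.
    """
    missing = [s for s in design.assignment if s not in set(matrix.sample_ids)]
    if missing:
        raise InputError(f"samples in design but not in matrix: {missing}")
    extra = [s for s in matrix.sample_ids if s not in design.assignment]
    if extra:
        raise InputError(f"samples in matrix but not in design: {extra}")

    means = {}
    ss = np.zeros(matrix.n_features)
    for cond in CONDITIONS:
        cols = design.samples_for(cond)
        block = matrix.data[cols].to_numpy()
        mu = block.mean(axis=1)
        means[cond] = mu
        ss += ((block - mu[:, None]) ** 2).sum(axis=1)
    d_g = design.residual_df
    means_df = pd.DataFrame(means, index=matrix.data.index, columns=list(CONDITIONS))
    s2 = pd.Series(ss / d_g, index=matrix.data.index, name="s2")
    return FitResult(means=means_df, s2=s2, d_g=d_g)


# ---------------------------------------------------------------------------
# Empirical-Bayes prior estimation and moderation
# ---------------------------------------------------------------------------


@dataclass
class EBPrior:
    """Scaled-inverse-chi-square prior on per-feature variances.

    ``d0`` may be ``+inf``, meaning all features share the variance ``s0_2``,
    or ``0``, the no-shrinkage limit recovering ordinary per-feature t-tests.
    """

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ConfigurationError(f"prior df must be >= 0, got {self.d0}")
        if not (self.s0_2 > 0):
            raise ConfigurationError(f"prior variance must be positive, got {self.s0_2}")


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def _log_chi2_mean_correction(df: float) -> float:
    # E[log(chi2_df / df)] = digamma(df/2) - log(df/2)
    return float(special.digamma(df / 2.0) - math.log(df / 2.0))


def estimate_eb_prior(s2, d_g: int) -> EBPrior:
    """Moment-match the variance prior on the log scale.

    Under the prior, ``log s_g^2`` has variance ``trigamma(d_g/2) +
    trigamma(d0/2)``; the observed spread of the log variances in excess of
    the known sampling component therefore identifies ``d0`` via a monotone
    root-find on the trigamma function.  ``s0^2`` follows from the mean of
    the log variances corrected by the corresponding digamma terms.  When the
    observed spread does not exceed the sampling component, ``d0 = +inf``.

    Zero or non-finite variances are excluded; at least two usable variances
    are required.
    """
    s2 = np.asarray(s2, dtype=float)
    usable = s2[np.isfinite(s2) & (s2 > 0)]
    if usable.size < 2:
        raise EstimationError(
            f"need at least 2 positive finite variances, got {usable.size}")

    z = np.log(usable)
    z_mean = float(z.mean())
    z_var = float(z.var(ddof=1))
    sampling_var = float(_trigamma(d_g / 2.0))
    excess = z_var - sampling_var

    if excess <= _trigamma(D0_CAP / 2.0):
        # No excess dispersion beyond (or at the cap of) what sampling alone
        # explains: variances are exchangeable, shrink completely.
        if np.all(usable == usable[0]):
            # All variances exactly equal: the common value is the estimate;
            # a sampling-bias correction presumes scatter that is absent.
            return EBPrior(d0=math.inf, s0_2=float(usable[0]))
        s0_2 = math.exp(z_mean - _log_chi2_mean_correction(d_g))
        return EBPrior(d0=math.inf, s0_2=s0_2)

    def f(d0: float) -> float:
        return float(_trigamma(d0 / 2.0)) - excess

    # trigamma is decreasing: f(lo) > 0 for small d0, f(hi) < 0 for large d0.
    lo = 1e-8
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > D0_CAP:
            return EBPrior(d0=math.inf,
                           s0_2=math.exp(z_mean - _log_chi2_mean_correction(d_g)))
    while f(lo) < 0:
        lo /= 2.0
    # xtol well below the 1e-8 residual target: |f'| is O(1) near the root
    d0 = float(optimize.brentq(f, lo, hi, xtol=1e-4 * D0_ROOT_TOL))
    s0_2 = math.exp(z_mean - _log_chi2_mean_correction(d_g)
                    + _log_chi2_mean_correction(d0))
    return EBPrior(d0=d0, s0_2=s0_2)


@dataclass
class ModeratedFit:
    """Moderated per-feature fit: the quantities every downstream test needs."""

    means: pd.DataFrame            # features x 4 condition means
    s2_tilde: pd.Series            # moderated variance per feature
    df_tilde: float                # moderated df, d0 + d_g (may be +inf)
    replicate_counts: dict         # condition -> n_c
    degenerate: pd.Series          # features excluded from classification
    d_g: int
    prior: EBPrior

    @property
    def feature_ids(self) -> list:
        return list(self.means.index)


def moderate(fit: FitResult, prior: EBPrior,
             replicate_counts: Mapping[str, int]) -> ModeratedFit:
    """Shrink per-feature variances towards the prior.

    With finite ``d0`` the moderated variance is the precision-weighted
    combination of prior and observed variance; with ``d0 = +inf`` every
    feature receives ``s0^2`` and infinite df (normal tails downstream).
    The ``d0 -> 0`` limit recovers the ordinary per-feature t-test.
    """
    if math.isinf(prior.d0):
        s2_tilde = pd.Series(prior.s0_2, index=fit.s2.index, name="s2_tilde")
        df_tilde = math.inf
    else:
        s2_tilde = ((prior.d0 * prior.s0_2 + fit.d_g * fit.s2)
                    / (prior.d0 + fit.d_g)).rename("s2_tilde")
        df_tilde = prior.d0 + fit.d_g
    return ModeratedFit(
        means=fit.means,
        s2_tilde=s2_tilde,
        df_tilde=df_tilde,
        replicate_counts=dict(replicate_counts),
        degenerate=fit.degenerate,
        d_g=fit.d_g,
        prior=prior,
    )


def fit_moderated(matrix: ExpressionMatrix, design: DesignMap,
                  prior: EBPrior | None = None) -> ModeratedFit:
    """Convenience chain: fit condition means, estimate the prior from the
    non-degenerate variances (unless one is supplied), and moderate."""
    fit = fit_condition_means(matrix, design)
    if prior is None:
        prior = estimate_eb_prior(fit.s2[~fit.degenerate].to_numpy(), fit.d_g)
    n_degenerate = int(fit.degenerate.sum())
    if n_degenerate:
        logger.warning("%d feature(s) have zero residual variance; flagged "
                       "degenerate and never classified", n_degenerate)
    return moderate(fit, prior, design.replicate_counts)
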