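"""The ten-form taxonomy of interplay and the per-feature classifier.

A 2x2 combination experiment admits a primary comparison — is the combined
effect ``mu_AB - mu_C`` smaller than, approximately equal to, or larger than
the sum of the single effects ``(mu_A - mu_C) + (mu_B - mu_C)`` — crossed
with a secondary comparison: which of the two constituents is effective on
its own.  Of the 12 resulting cells, two are logically impossible under the
premise that the combination is effective (both constituents inert and the
interaction zero or negative would make the combination inert too), leaving
ten forms of interplay:

=====================  ==========  ==========  ===============
secondary \\ primary    sum-smaller sum-equal   sum-larger
=====================  ==========  ==========  ===============
A and B effective      antagonism  additive    synergism
A inert, B effective   reductive   redundance  potentiation (by A)
B inert, A effective   reductive   redundance  potentiation (by B)
A and B inert          impossible  impossible  emergent
=====================  ==========  ==========  ===============

Each form exists in an up- and a down-regulated variant (every strict
inequality mirrored; near-equality is direction-free).  A form is a
conjunction of partial hypotheses — one-sided contrast tests for the strict
relations, TOST equivalence tests for the near-equalities — compounded with
an intersection-union test: the compound p-value is the max of the partial
p-values and a feature displays the form iff the compound p < alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import ModeratedFit
from .stats import (A_VS_C, AB_VS_C, B_VS_C, INTERACTION, Contrast, TostSpec,
                    compound_iut, contrast_pvalues, tost_pvalues)

__all__ = [
    "PATTERN_NAMES", "Config", "PatternSpec", "Assignment",
    "ClassificationResult", "taxonomy_grid", "enumerate_patterns",
    "classify_feature", "classify_dataset", "summarize",
]

#: The ten base forms, in the display order of the summary table.
PATTERN_NAMES = (
    "synergism",
    "additive",
    "antagonism",
    "potentiation_by_A",
    "redundance_of_A",
    "reductive_by_A",
    "potentiation_by_B",
    "redundance_of_B",
    "reductive_by_B",
    "emergent",
)

# Relations (A-C, B-C, interaction) defining each up-regulated form:
# ">" strict inequality, "~" near-equality within [-eps, eps].
_BASE_RELATIONS = {
    "synergism":          (">", ">", ">"),
    "additive":           (">", ">", "~"),
    "antagonism":         (">", ">", "<"),
    "potentiation_by_A":  ("~", ">", ">"),
    "redundance_of_A":    ("~", ">", "~"),
    "reductive_by_A":     ("~", ">", "<"),
    "potentiation_by_B":  (">", "~", ">"),
    "redundance_of_B":    (">", "~", "~"),
    "reductive_by_B":     (">", "~", "<"),
    "emergent":           ("~", "~", ">"),
}

#: The two cells excluded from the 12 logical combinations: both
#: constituents inert with a zero or negative interaction would contradict
#: an effective combination.
IMPOSSIBLE_CELLS = (("~", "~", "<"), ("~", "~", "~"))


def taxonomy_grid():
    """All 12 logical (A-C, B-C, interaction) relation triples with their
    form name, or None for the two impossible cells."""
    by_relation = {rel: name for name, rel in _BASE_RELATIONS.items()}
    grid = []
    for a in (">", "~"):
        for b in (">", "~"):
            for i in ("<", "~", ">"):
                grid.append(((a, b, i), by_relation.get((a, b, i))))
    return grid


@dataclass
class Config:
    """Classifier settings.

    alpha
        Significance level of every partial test (and hence an upper bound
        on the compound level).  Must lie in (0, 0.5).
    eps
        Half-width of the symmetric tolerance interval for near-equality,
        in log2 units.
    require_ab_effective
        Append an explicit one-sided AB-vs-C partial to every pattern,
        turning the taxonomy's premise of an effective combination into a
        tested component instead of an assumption.
    fdr
        If True, Benjamini-Hochberg-adjust the compound p-values across
        features within each pattern before applying the alpha cutoff.
    """

    alpha: float = 0.05
    eps: float = 0.15
    require_ab_effective: bool = True
    fdr: bool = False

    def __post_init__(self) -> None:
        from .model import ConfigurationError
        if not (0.0 < self.alpha < 0.5):
            raise ConfigurationError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not (self.eps > 0):
            raise ConfigurationError(f"eps must be positive, got {self.eps}")


@dataclass(frozen=True)
class PatternSpec:
    """One direction-specific form of interplay as a list of partial tests.

    ``partials`` holds ``(contrast, kind)`` pairs with kind in
    {"greater", "less", "near_equal"}.
    """

    name: str
    direction: str            # "up" or "down"
    partials: tuple

    @property
    def key(self) -> str:
        return f"{self.name}:{self.direction}"


_KIND_FLIP = {"greater": "less", "less": "greater", "near_equal": "near_equal"}
_REL_TO_KIND = {">": "greater", "<": "less", "~": "near_equal"}


def enumerate_patterns(config: Config) -> list[PatternSpec]:
    """Build the 20 direction-specific pattern specifications.

    The down-regulated variants mirror every strict inequality and leave
    near-equality partials unchanged.  When ``config.require_ab_effective``
    an AB-vs-C partial ("greater" for up, "less" for down) is appended.
    """
    specs = []
    for direction in ("up", "down"):
        for name in PATTERN_NAMES:
            rel = _BASE_RELATIONS[name]
            partials = []
            for contrast, r in zip((A_VS_C, B_VS_C, INTERACTION), rel):
                kind = _REL_TO_KIND[r]
                if direction == "down":
                    kind = _KIND_FLIP[kind]
                partials.append((contrast, kind))
            if config.require_ab_effective:
                partials.append(
                    (AB_VS_C, "greater" if direction == "up" else "less"))
            specs.append(PatternSpec(name=name, direction=direction,
                                     partials=tuple(partials)))
    return specs


@dataclass
class Assignment:
    """Classification outcome for a single feature."""

    feature_id: object
    compound_p: dict          # pattern key -> compound p-value
    accepted: tuple           # pattern keys with compound p < alpha
    label: str                # unique form, "none", "ambiguous" or "degenerate"
    direction: str            # "up"/"down" when label is unique, else ""
    status: str = "ok"        # "ok" or "degenerate"


@dataclass
class ClassificationResult:
    """Whole-dataset classification: per-feature per-pattern compound
    p-values, acceptance matrix and labels, plus contrast estimates."""

    compound_p: pd.DataFrame      # features x 20 pattern keys
    accepted: pd.DataFrame        # boolean, same shape
    labels: pd.Series             # per-feature label
    directions: pd.Series         # per-feature direction ("" if not unique)
    estimates: pd.DataFrame       # features x 4 contrast estimates
    config: Config

    @property
    def feature_ids(self) -> list:
        return list(self.compound_p.index)

    def assignment(self, feature) -> Assignment:
        row = self.compound_p.loc[feature]
        acc = tuple(self.accepted.columns[self.accepted.loc[feature]])
        status = "degenerate" if self.labels.loc[feature] == "degenerate" else "ok"
        return Assignment(feature_id=feature,
                          compound_p=row.to_dict(),
                          accepted=acc,
                          label=self.labels.loc[feature],
                          direction=self.directions.loc[feature],
                          status=status)


def _partial_p_arrays(fit: ModeratedFit, config: Config) -> dict:
    """Compute each distinct partial test once, vectorised over features."""
    spec = TostSpec(config.eps)
    arrays = {}
    for contrast in (A_VS_C, B_VS_C, INTERACTION, AB_VS_C):
        arrays[(contrast.label, "greater")] = contrast_pvalues(fit, contrast, "greater")
        arrays[(contrast.label, "less")] = contrast_pvalues(fit, contrast, "less")
    for contrast in (A_VS_C, B_VS_C, INTERACTION):
        arrays[(contrast.label, "near_equal")] = tost_pvalues(fit, contrast, spec)
    return arrays


def classify_dataset(fit: ModeratedFit, config: Config | None = None) -> ClassificationResult:
    """Classify every feature of a moderated fit.

    For each of the 20 direction-specific patterns the listed partial tests
    are evaluated at level alpha and compounded by the intersection-union
    rule (compound p = max of partial p-values).  A feature's label is the
    unique accepted pattern, "none" if no pattern is accepted, "ambiguous"
    if several are (possible when standard errors are small relative to the
    tolerance interval), and "degenerate" for features with zero residual
    variance, which are never tested.
    """
    config = config or Config()
    specs = enumerate_patterns(config)
    index = fit.means.index
    n = len(index)

    if n == 0:
        empty_p = pd.DataFrame(index=index, columns=[s.key for s in specs], dtype=float)
        return ClassificationResult(
            compound_p=empty_p, accepted=empty_p.astype(bool).fillna(False),
            labels=pd.Series(dtype=object, index=index),
            directions=pd.Series(dtype=object, index=index),
            estimates=pd.DataFrame(index=index), config=config)

    partial = _partial_p_arrays(fit, config)
    degen = fit.degenerate.to_numpy()

    compound = {}
    for spec in specs:
        stack = np.vstack([partial[(c.label, kind)] for c, kind in spec.partials])
        compound[spec.key] = stack.max(axis=0)
    compound_p = pd.DataFrame(compound, index=index)

    if config.fdr:
        from statsmodels.stats.multitest import multipletests
        adjusted = {}
        for key in compound_p.columns:
            p = compound_p[key].to_numpy()
            ok = ~np.isnan(p)
            q = np.full_like(p, np.nan)
            if ok.any():
                q[ok] = multipletests(p[ok], method="fdr_bh")[1]
            adjusted[key] = q
        decision_p = pd.DataFrame(adjusted, index=index)
    else:
        decision_p = compound_p

    accepted = (decision_p < config.alpha).fillna(False)
    accepted.loc[degen] = False

    acc = accepted.to_numpy()
    n_acc = acc.sum(axis=1)
    labels = np.where(n_acc == 0, "none", "ambiguous").astype(object)
    directions = np.full(n, "", dtype=object)
    unique_rows = np.nonzero(n_acc == 1)[0]
    keys = np.array([s.key for s in specs], dtype=object)
    for i in unique_rows:
        key = keys[acc[i]][0]
        name, direction = key.split(":")
        labels[i] = name
        directions[i] = direction
    labels[degen] = "degenerate"
    directions[degen] = ""

    from .stats import contrast_estimates
    est = {c.label: contrast_estimates(fit, c)[0]
           for c in (A_VS_C, B_VS_C, INTERACTION, AB_VS_C)}
    estimates = pd.DataFrame(est, index=index)

    return ClassificationResult(
        compound_p=compound_p,
        accepted=accepted,
        labels=pd.Series(labels, index=index, name="label"),
        directions=pd.Series(directions, index=index, name="direction"),
        estimates=estimates,
        config=config,
    )


def classify_feature(fit: ModeratedFit, feature, config: Config | None = None) -> Assignment:
    """Classify a single feature (see :func:`classify_dataset`)."""
    config = config or Config()
    result = classify_dataset(fit, config)
    return result.assignment(feature)


def summarize(result: ClassificationResult) -> pd.DataFrame:
    """Count uniquely classified features per form and direction.

    Rows are the ten forms plus a total row; columns are UP and DOWN counts.
    Ambiguous and degenerate features are not counted in any form.
    """
    counts = pd.DataFrame(0, index=list(PATTERN_NAMES) + ["total"],
                          columns=["UP", "DOWN"], dtype=int)
    for name in PATTERN_NAMES:
        mask = result.labels == name
        counts.loc[name, "UP"] = int((mask & (result.directions == "up")).sum())
        counts.loc[name, "DOWN"] = int((mask & (result.directions == "down")).sum())
    counts.loc["total"] = counts.loc[list(PATTERN_NAMES)].sum()
    return counts
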