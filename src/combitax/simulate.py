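"""Synthetic 2x2 factorial expression data with planted interplay patterns.

The generator emulates the structure of a small-replicate microarray
combination experiment: four conditions (control C, singles A and B,
combination AB) with a few replicates each, Gaussian noise on the log2
scale, and per-feature variances drawn from the scaled-inverse-chi-square
prior the moderation model assumes.  Each non-null feature is planted with
condition means that satisfy one taxonomy cell exactly: strict single
effects at +/-effect_size, near-equality components at exactly 0, and the
interaction set so that the cell's primary comparison holds while the
combination remains effective.  Ground-truth labels are returned so
classifier output can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CONDITIONS, DesignMap, ExpressionMatrix
from .taxonomy import PATTERN_NAMES

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_dataset",
           "evaluate_recovery", "PATTERN_EFFECTS", "pattern_means"]

# (a, b, i) multipliers of effect_size for the up-regulated variant of each
# form: a = mu_A - mu_C, b = mu_B - mu_C, i = interaction.  The reductive
# cells use a half-magnitude negative interaction so the combined effect
# (b + i or a + i) stays strictly positive, as the taxonomy premise requires.
PATTERN_EFFECTS = {
    "synergism":          (1.0, 1.0, 1.0),
    "additive":           (1.0, 1.0, 0.0),
    "antagonism":         (1.0, 1.0, -1.0),
    "potentiation_by_A":  (0.0, 1.0, 1.0),
    "redundance_of_A":    (0.0, 1.0, 0.0),
    "reductive_by_A":     (0.0, 1.0, -0.5),
    "potentiation_by_B":  (1.0, 0.0, 1.0),
    "redundance_of_B":    (1.0, 0.0, 0.0),
    "reductive_by_B":     (1.0, 0.0, -0.5),
    "emergent":           (0.0, 0.0, 1.0),
}


def pattern_means(name: str, direction: str, effect_size: float,
                  baseline: float = 0.0) -> dict:
    """True condition means (C, A, B, AB) for one planted pattern."""
    a, b, i = PATTERN_EFFECTS[name]
    sign = 1.0 if direction == "up" else -1.0
    a, b, i = sign * a * effect_size, sign * b * effect_size, sign * i * effect_size
    return {"C": baseline, "A": baseline + a, "B": baseline + b,
            "AB": baseline + a + b + i}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a three-replicate microarray combination experiment:
    n = 3 per condition, unit log2 effects for strict components, and a
    moderately informative variance prior (d0 = 4, s0^2 = 0.04, i.e. a
    typical residual SD of 0.2 log2 units).  ``variance_prior`` with
    ``d0 = inf`` gives every feature the same variance ``s0^2``.
    ``pattern_block_sizes`` maps ``(name, direction)`` to a feature count.
    """

    seed: int
    n_per_condition: int = 3
    pattern_block_sizes: Mapping = field(default_factory=dict)
    n_null: int = 0
    effect_size: float = 1.0
    baseline: float = 0.0
    variance_prior: tuple = (4.0, 0.04)
    boundary_eps: float | None = None   # plant near-equality components at
                                        # +/-eps instead of 0 (size checks)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        total = sum(self.pattern_block_sizes.values()) + self.n_null
        if total <= 0:
            raise ValueError("simulation must contain at least one feature")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        for (name, direction), count in self.pattern_block_sizes.items():
            if name not in PATTERN_NAMES:
                raise ValueError(f"unknown pattern {name!r}")
            if direction not in ("up", "down"):
                raise ValueError(f"unknown direction {direction!r}")
            if count < 0:
                raise ValueError("block sizes must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth per simulated feature: planted label ("name:direction"
    or "null"), the true condition means, and the true residual variance."""

    table: pd.DataFrame   # columns: label, mu_C, mu_A, mu_B, mu_AB, sigma2

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def _draw_variances(rng: np.random.Generator, n: int, prior: tuple) -> np.ndarray:
    d0, s0_2 = prior
    if math.isinf(d0):
        return np.full(n, s0_2)
    return s0_2 * d0 / rng.chisquare(d0, size=n)


def simulate_dataset(config: SimulationConfig):
    """Generate ``(ExpressionMatrix, DesignMap, SyntheticTruth)``.

    Per feature a residual variance is drawn from the prior, then every
    observation is Normal(mu_condition, sigma_g^2), i.i.d.  Output is
    bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_condition

    rows = []
    for (name, direction), count in sorted(config.pattern_block_sizes.items()):
        mu = pattern_means(name, direction, config.effect_size, config.baseline)
        if config.boundary_eps is not None:
            # shift planted near-equality components to the tolerance edge
            a, b, i = PATTERN_EFFECTS[name]
            sign = 1.0 if direction == "up" else -1.0
            edge = sign * config.boundary_eps
            if a == 0.0:
                mu["A"] = mu["C"] + edge
            if b == 0.0:
                mu["B"] = mu["C"] + edge
            if i == 0.0:
                mu["AB"] = mu["A"] + mu["B"] - mu["C"] + edge
        for _ in range(count):
            rows.append((f"{name}:{direction}", mu))
    null_mu = {c: config.baseline for c in CONDITIONS}
    for _ in range(config.n_null):
        rows.append(("null", null_mu))

    n_features = len(rows)
    sigma2 = _draw_variances(rng, n_features, config.variance_prior)

    sample_ids = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(n)]
    assignment = {f"{cond}_{r + 1}": cond for cond in CONDITIONS for r in range(n)}

    mu_matrix = np.empty((n_features, 4 * n))
    for j, cond in enumerate(CONDITIONS):
        mu_col = np.array([mu[cond] for _, mu in rows])
        mu_matrix[:, j * n:(j + 1) * n] = mu_col[:, None]
    noise = rng.standard_normal((n_features, 4 * n)) * np.sqrt(sigma2)[:, None]
    values = mu_matrix + noise

    feature_ids = [f"feat_{i:06d}" for i in range(n_features)]
    matrix = ExpressionMatrix.from_dataframe(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids))
    design = DesignMap(assignment=assignment)

    truth = pd.DataFrame({
        "label": [label for label, _ in rows],
        "mu_C": [mu["C"] for _, mu in rows],
        "mu_A": [mu["A"] for _, mu in rows],
        "mu_B": [mu["B"] for _, mu in rows],
        "mu_AB": [mu["AB"] for _, mu in rows],
        "sigma2": sigma2,
    }, index=feature_ids)
    return matrix, design, SyntheticTruth(table=truth)


def evaluate_recovery(truth: SyntheticTruth, result):
    """Score classifier output against planted truth.

    Returns ``(confusion, metrics)``.  ``confusion`` is a 21x21 matrix over
    the 20 direction-specific patterns plus "none" (rows = planted, columns
    = unique assigned label, with ambiguous/degenerate counted as "none").
    ``metrics`` has one row per pattern:

    sensitivity
        Fraction of planted features whose accepted set contains the planted
        pattern.  This is the power of the pattern's compound test; it is
        the right recovery measure because a feature whose true near-equality
        contrast also crosses the strict threshold (probability ~alpha) is
        co-accepted by a neighbouring pattern and reported ambiguous rather
        than mislabelled.
    sensitivity_unique
        Fraction of planted features carrying the planted pattern as their
        unique label (ambiguity counts against it).
    specificity
        Fraction of features NOT planted with the pattern whose accepted set
        excludes it.
    """
    planted = truth.labels.replace({"null": "none"})
    if set(planted.index) != set(result.labels.index):
        raise ValueError("feature sets of truth and classification differ")
    assigned = pd.Series(
        np.where(result.labels.isin(PATTERN_NAMES),
                 result.labels.astype(str) + ":" + result.directions.astype(str),
                 "none"),
        index=result.labels.index).loc[planted.index]
    accepted = result.accepted.loc[planted.index]

    keys = [f"{n}:{d}" for d in ("up", "down") for n in PATTERN_NAMES] + ["none"]
    confusion = pd.DataFrame(0, index=keys, columns=keys, dtype=int)
    for p, a in zip(planted, assigned):
        confusion.loc[p, a] += 1

    metrics = {}
    total = len(planted)
    for key in keys[:-1]:
        mask = (planted == key).to_numpy()
        planted_n = int(mask.sum())
        acc = accepted[key].to_numpy() if key in accepted.columns else np.zeros(total, bool)
        metrics[key] = {
            "sensitivity": float(acc[mask].mean()) if planted_n else np.nan,
            "sensitivity_unique": (float((assigned[mask] == key).mean())
                                   if planted_n else np.nan),
            "specificity": (float(1.0 - acc[~mask].mean())
                            if total > planted_n else np.nan),
        }
    return confusion, pd.DataFrame(metrics).T
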