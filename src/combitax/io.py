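"""Readers, writers and the end-to-end pipeline entry point.

File formats are deliberately plain: the expression matrix is a TSV with a
header row, feature ids in the first column and one column per sample (log2
scale, e.g. RMA output); the targets file is a two-column TSV mapping each
sample id to its condition.  Study-specific condition labels (for instance
UNSTIMULATED / CURDLAN / GM-CSF / COMBINATION) are renamed to the canonical
C / A / B / AB through a user-supplied condition map.  Every run emits a
JSON metadata sidecar sufficient to reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import (CONDITIONS, DesignMap, ExpressionMatrix, InputError,
                    fit_moderated)
from .taxonomy import (ClassificationResult, Config, classify_dataset,
                       summarize)

logger = logging.getLogger("combitax")

__all__ = ["read_expression", "read_targets", "write_expression",
           "write_targets", "write_truth", "read_truth", "run_classify",
           "RunMetadata"]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_expression(path) -> ExpressionMatrix:
    """Read a features x samples log2 expression TSV (header required).

    Duplicate feature ids and non-numeric cells are errors; rows with
    missing values are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate feature id {dup!r}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    # distinguish genuinely missing cells from unparseable text
    stripped = df.astype(str).apply(lambda col: col.str.strip())
    bad = coerced.isna() & df.notna() & (stripped != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r}")
    # float() is correctly rounded (pd.to_numeric's parser can be 1 ulp off)
    numeric = df.astype(float)
    return ExpressionMatrix.from_dataframe(numeric)


def read_targets(path, condition_map: dict | None = None) -> DesignMap:
    """Read a two-column sample-to-condition TSV and build a DesignMap.

    ``condition_map`` renames study labels to C/A/B/AB before validation.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise InputError(f"{path}: expected 2 columns, found {df.shape[1]}")
    first = tuple(x.strip().lower() for x in df.iloc[0])
    if first in (("sample", "condition"), ("sample_id", "condition")):
        df = df.iloc[1:]
    assignment = {}
    cmap = condition_map or {}
    for _, (sample, cond) in df.iterrows():
        sample, cond = sample.strip(), cond.strip()
        cond = cmap.get(cond, cond)
        if sample in assignment:
            raise InputError(f"{path}: duplicate sample id {sample!r}")
        assignment[sample] = cond
    return DesignMap(assignment=assignment)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    # full precision so a write-read round trip is exact
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")  # default repr round-trips floats exactly


def write_targets(design: DesignMap, path) -> None:
    with open(path, "w") as fh:
        for sample, cond in design.assignment.items():
            fh.write(f"{sample}\t{cond}\n")


def write_truth(truth, path) -> None:
    df = truth.table.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_truth(path):
    from .simulate import SyntheticTruth
    # keep_default_na: the literal label "null" must survive parsing
    table = pd.read_csv(path, sep="\t", index_col=0,
                        keep_default_na=False, na_values=[""])
    return SyntheticTruth(table=table)


@dataclass
class RunMetadata:
    """Everything needed to reproduce a classification run exactly."""

    alpha: float
    eps: float
    require_ab_effective: bool
    fdr: bool
    seed: int | None
    input_digests: dict
    version: str
    n_features: int
    n_dropped_missing: int
    n_degenerate: int
    prior_d0: float
    prior_s0_2: float
    condition_map: dict
    moderation: str = "plain empirical Bayes (no trend, no robust fitting)"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["prior_d0"] = "inf" if math.isinf(self.prior_d0) else self.prior_d0
        return json.dumps(d, indent=2, sort_keys=True)


def _format_results(result: ClassificationResult) -> pd.DataFrame:
    out = pd.DataFrame(index=result.compound_p.index)
    out["label"] = result.labels
    out["direction"] = result.directions
    accepted_p = []
    for feat in out.index:
        label = result.labels.loc[feat]
        direction = result.directions.loc[feat]
        key = f"{label}:{direction}"
        if direction and key in result.compound_p.columns:
            accepted_p.append(result.compound_p.loc[feat, key])
        else:
            accepted_p.append(np.nan)
    out["p_accepted"] = accepted_p
    for col in result.estimates.columns:
        out[f"estimate_{col}"] = result.estimates[col]
    for col in result.compound_p.columns:
        out[f"p_{col}"] = result.compound_p[col]
    return out


def write_results(result: ClassificationResult, path) -> None:
    """Write the per-feature results TSV: label, direction, compound p of
    the accepted pattern, the four contrast estimates and all 20 compound
    p-values.  A ``#`` header block documents the columns."""
    out = _format_results(result)
    with open(path, "w") as fh:
        fh.write("# combitax per-feature interplay classification\n")
        fh.write("# label: unique accepted form, 'none', 'ambiguous' or 'degenerate'\n")
        fh.write("# p_accepted: compound p-value of the accepted form (intersection-union max)\n")
        fh.write("# estimate_*: moderated contrast estimates, log2 units\n")
        fh.write("# p_<form>:<direction>: compound p-value of every form\n")
        out.index.name = "feature_id"
        formatted = out.copy()
        for col in formatted.columns:
            if col.startswith("p_"):
                formatted[col] = formatted[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.6e}")
            elif col.startswith("estimate_"):
                formatted[col] = formatted[col].map(lambda v: f"{v:.6g}")
        formatted.to_csv(fh, sep="\t")


def run_classify(matrix_path, targets_path, config: Config | None = None,
                 condition_map: dict | None = None, out_prefix=None,
                 seed: int | None = None):
    """End-to-end pipeline: read, fit, moderate, classify, summarise.

    Returns ``(ClassificationResult, summary DataFrame, RunMetadata)``; when
    ``out_prefix`` is given, also writes ``<prefix>.results.tsv``,
    ``<prefix>.summary.tsv`` and ``<prefix>.meta.json``.
    """
    config = config or Config()
    matrix = read_expression(matrix_path)
    design = read_targets(targets_path, condition_map)
    fit = fit_moderated(matrix, design)
    result = classify_dataset(fit, config)
    summary = summarize(result)

    meta = RunMetadata(
        alpha=config.alpha, eps=config.eps,
        require_ab_effective=config.require_ab_effective, fdr=config.fdr,
        seed=seed,
        input_digests={"matrix": _sha256(matrix_path),
                       "targets": _sha256(targets_path)},
        version=__version__,
        n_features=matrix.n_features,
        n_dropped_missing=matrix.n_dropped,
        n_degenerate=int(fit.degenerate.sum()),
        prior_d0=fit.prior.d0,
        prior_s0_2=fit.prior.s0_2,
        condition_map=dict(condition_map or {}),
    )

    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_results(result, f"{prefix}.results.tsv")
        summary.to_csv(f"{prefix}.summary.tsv", sep="\t")
        with open(f"{prefix}.meta.json", "w") as fh:
            fh.write(meta.to_json() + "\n")
        logger.info("wrote %s.{results.tsv,summary.tsv,meta.json}", prefix)
    return result, summary, meta
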