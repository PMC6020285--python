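"""Per-gene two-condition differential expression.

Fold change is the ratio of arithmetic condition means on the linear
intensity scale (the convention used by array analysis consoles), while the
t-test is computed on log2-transformed intensities where the additive noise
model is closer to the truth. Multiplicity is handled by Benjamini-Hochberg
step-up adjustment over all genes in the table, and significance gating
uses a strict ``fdr < alpha`` inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix, ResultTable

__all__ = [
    "Design",
    "DETable",
    "make_design",
    "fold_change",
    "adjust_bh",
    "de_test",
    "significant",
    "de_result_table",
    "read_de_table",
    "UP",
    "DOWN",
    "FLAT",
]

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
FLAT = "flat"

#: smallest positive normal double; reported instead of an exact zero p-value
_TINY = float(np.finfo(float).tiny)

_DE_COLUMNS = ["gene", "mean_a", "mean_b", "fc", "log2fc", "p", "fdr", "direction"]


@dataclass(frozen=True)
class Design:
    """A two-condition comparison: condition_a / condition_b fold change."""

    condition_a: str
    condition_b: str
    replicates: Mapping[str, int]

    def __post_init__(self):
        if self.condition_a == self.condition_b:
            raise ValidationError("condition_a and condition_b must differ")
        for cond in (self.condition_a, self.condition_b):
            if self.replicates.get(cond, 0) < 1:
                raise ValidationError(f"condition '{cond}' has no samples")


def make_design(matrix: ExpressionMatrix, condition_a: str, condition_b: str) -> Design:
    """Build a validated Design for two condition labels of a matrix."""
    counts = {c: len(matrix.samples_of(c)) for c in (condition_a, condition_b)}
    for cond, n in counts.items():
        if n == 0:
            raise ValidationError(
                f"condition '{cond}' not present in matrix design "
                f"(available: {matrix.conditions})"
            )
    return Design(condition_a=condition_a, condition_b=condition_b, replicates=counts)


@dataclass
class DETable:
    """Differential-expression results for every gene of one comparison.

    ``frame`` is indexed by gene with columns mean_a, mean_b, fc, log2fc,
    p, fdr and direction; fold change is oriented numerator/denominator.
    """

    comparison: str
    numerator: str
    denominator: str
    frame: pd.DataFrame

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            raise ValidationError("DE table contains duplicate genes")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)


def fold_change(matrix: ExpressionMatrix, design: Design) -> pd.DataFrame:
    """Per-gene linear fold change: mean(condition_a) / mean(condition_b).

    Returns a frame indexed by gene with columns mean_a, mean_b, fc.
    """
    samples_a = matrix.samples_of(design.condition_a)
    samples_b = matrix.samples_of(design.condition_b)
    if not samples_a or not samples_b:
        raise ValidationError("both conditions must be present in the matrix")
    mean_a = matrix.values[samples_a].mean(axis=1)
    mean_b = matrix.values[samples_b].mean(axis=1)
    return pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "fc": mean_a / mean_b})


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Standard definition: sort ascending, q_i = p_(i)·m/i, take the running
    minimum from the largest rank down, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    matrix: ExpressionMatrix, design: Design, method: str = "welch_t"
) -> DETable:
    """Two-sided t-test per gene on log2 intensities, plus FC and BH-FDR.

    ``method`` is ``welch_t`` (unequal variances, default) or ``student_t``
    (pooled variance). Degenerate conventions: identical groups give p = 1;
    zero within-group variance with unequal means gives the smallest
    positive double instead of an exact zero (a warning is logged).
    """
    if method not in ("welch_t", "student_t"):
        raise ValidationError(f"unknown test method '{method}'")
    samples_a = matrix.samples_of(design.condition_a)
    samples_b = matrix.samples_of(design.condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("de_test requires at least 2 replicates per condition")

    log2v = np.log2(matrix.values.to_numpy(dtype=float))
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    a = log2v[:, [cols[s] for s in samples_a]]
    b = log2v[:, [cols[s] for s in samples_b]]

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=(method == "student_t"))
        p = np.asarray(res.pvalue, dtype=float)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    mean_a_log = a.mean(axis=1)
    mean_b_log = b.mean(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = degenerate & (mean_a_log == mean_b_log)
    sep_means = degenerate & (mean_a_log != mean_b_log)
    p[equal_means] = 1.0
    if sep_means.any():
        logger.warning(
            "%d gene(s) with zero within-group variance and unequal means; "
            "reporting smallest positive p instead of 0",
            int(sep_means.sum()),
        )
        p[sep_means] = _TINY
    n_zero = int(np.sum(p <= 0))
    if n_zero:
        logger.warning(
            "%d exact-zero p-value(s) replaced by smallest positive double", n_zero
        )
        p[p <= 0] = _TINY
    p = np.minimum(p, 1.0)

    fc = fold_change(matrix, design)
    frame = fc.copy()
    frame["log2fc"] = np.log2(frame["fc"].to_numpy())
    frame["p"] = p
    frame["fdr"] = adjust_bh(p)
    frame["direction"] = np.select(
        [frame["fc"] > 1, frame["fc"] < 1], [UP, DOWN], default=FLAT
    )
    return DETable(
        comparison=f"{design.condition_a}_vs_{design.condition_b}",
        numerator=design.condition_a,
        denominator=design.condition_b,
        frame=frame[["mean_a", "mean_b", "fc", "log2fc", "p", "fdr", "direction"]],
    )


def significant(table: DETable, alpha: float) -> set[tuple[str, str]]:
    """Genes with fdr strictly below alpha, paired with their direction.

    Flat genes (fc exactly 1) are never returned: their direction is
    undefined.
    """
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    f = table.frame
    keep = (f["fdr"] < alpha) & (f["direction"] != FLAT)
    return set(zip(f.index[keep], f.loc[keep, "direction"]))


def de_result_table(table: DETable, **extra_metadata) -> ResultTable:
    """Package a DETable for writing (gene column first, metadata block)."""
    frame = table.frame.reset_index(names="gene")[_DE_COLUMNS]
    meta = {
        "comparison": table.comparison,
        "numerator": table.numerator,
        "denominator": table.denominator,
        **extra_metadata,
    }
    return ResultTable(frame=frame, metadata=meta)


def read_de_table(path) -> DETable:
    """Re-load a DE TSV written via ``de_result_table`` + ``write_table``."""
    from .io import read_table
    from .errors import SchemaError

    rt = read_table(path)
    missing = [c for c in _DE_COLUMNS if c not in rt.frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing DE columns {missing}")
    frame = rt.frame.set_index("gene")
    return DETable(
        comparison=str(rt.metadata.get("comparison", "unknown")),
        numerator=str(rt.metadata.get("numerator", "a")),
        denominator=str(rt.metadata.get("denominator", "b")),
        frame=frame,
    )
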