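"""Bench-validation arithmetic: 2^-ddCt relative quantification,
Holm-Sidak-corrected t-tests, and tissue-compartment percent expression.

The Livak 2^-ddCt convention: per sample, dCt = Ct(target) − Ct(reference
housekeeping gene); the calibrator is the mean control-group dCt; each
sample's relative quantity is RQ = 2^−(dCt − calibrator), so control RQs
average near 1 and the group fold change is mean(treated RQ)/mean(control
RQ). Group comparison uses a two-tailed Welch t-test on the RQ scale by
default (matching fold-change ± SEM presentation), with a dCt-scale option.

Compartment partitioning expresses each tissue's reference-normalized
expression as a percentage of the summed expression across the two
compartments (mesenchyme + ectoderm = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError, ValidationError
from .io import ResultTable

__all__ = [
    "QpcrSample",
    "DdctResult",
    "CompartmentExpression",
    "ddct_fold",
    "holm_sidak",
    "compartment_percent",
    "qpcr_table",
    "TREATED",
    "CONTROL",
]

TREATED = "treated"
CONTROL = "control"

_TINY = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class QpcrSample:
    """One well: target and housekeeping Ct values for one sample."""

    sample: str
    group: str  # treated | control
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if self.group not in (TREATED, CONTROL):
            raise ValidationError(f"group must be '{TREATED}' or '{CONTROL}', got '{self.group}'")
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive and finite, got {v}")


@dataclass
class DdctResult:
    """Per-sample relative quantities plus the group-level summary."""

    rq: dict[str, float]  # sample -> 2^-(dCt - calibrator)
    dct: dict[str, float]
    calibrator: float  # mean control dCt
    fold_change: float  # mean treated RQ / mean control RQ
    p: float


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t p-value with the package's degenerate conventions:
    identical-variance-free groups with equal means give p = 1; an exact
    zero is replaced by the smallest positive double."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else _TINY
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if not np.isfinite(p):
        return 1.0
    return min(max(p, _TINY), 1.0)


def ddct_fold(samples: list[QpcrSample], scale: str = "rq") -> DdctResult:
    """Livak relative quantification for one gene.

    ``scale`` selects the t-test input: ``rq`` (default, per-sample
    relative quantities) or ``dct`` (per-sample dCt values).
    """
    if scale not in ("rq", "dct"):
        raise ValidationError(f"unknown test scale '{scale}'")
    groups: dict[str, list[QpcrSample]] = {TREATED: [], CONTROL: []}
    for s in samples:
        groups[s.group].append(s)
    for name, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"group '{name}' needs >= 2 samples, has {len(members)}")

    dct = {s.sample: s.ct_target - s.ct_reference for s in samples}
    calibrator = float(np.mean([dct[s.sample] for s in groups[CONTROL]]))
    rq = {name: float(2.0 ** -(d - calibrator)) for name, d in dct.items()}

    rq_t = np.array([rq[s.sample] for s in groups[TREATED]])
    rq_c = np.array([rq[s.sample] for s in groups[CONTROL]])
    fold = float(rq_t.mean() / rq_c.mean())
    if scale == "rq":
        p = _welch_p(rq_t, rq_c)
    else:
        p = _welch_p(
            np.array([dct[s.sample] for s in groups[TREATED]]),
            np.array([dct[s.sample] for s in groups[CONTROL]]),
        )
    return DdctResult(rq=rq, dct=dct, calibrator=calibrator, fold_change=fold, p=p)


def holm_sidak(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Sidak adjustment.

    Sorted ascending, adjusted_i = max_{j<=i} (1 − (1 − p_(j))^(m−j+1)),
    capped at 1 and mapped back to input order. Rejection uses a strict
    ``adjusted < alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, alpha=alpha, method="holm-sidak")[1]
    return adjusted, adjusted < alpha


@dataclass
class CompartmentExpression:
    """Reference-normalized expression split across two tissue compartments."""

    gene: str
    expr_mesenchyme: float
    expr_ectoderm: float
    pct_mesenchyme: float
    pct_ectoderm: float


def compartment_percent(
    expr_mes: float, expr_ect: float, gene: str = ""
) -> CompartmentExpression:
    """Percent of total (two-compartment) expression in each compartment."""
    if expr_mes < 0 or expr_ect < 0:
        raise ValidationError("compartment expression ratios must be >= 0")
    total = expr_mes + expr_ect
    if total == 0:
        raise ValidationError("both compartments are zero; percent split undefined")
    pct_mes = 100.0 * expr_mes / total
    return CompartmentExpression(
        gene=gene,
        expr_mesenchyme=expr_mes,
        expr_ectoderm=expr_ect,
        pct_mesenchyme=pct_mes,
        pct_ectoderm=100.0 - pct_mes,
    )


_CT_COLUMNS = ["sample", "group", "gene", "ct_target", "ct_reference"]


def qpcr_table(ct_frame: pd.DataFrame, alpha: float = 0.05, scale: str = "rq") -> ResultTable:
    """Run ddct_fold per gene of a long-format Ct table and apply
    Holm-Sidak correction across genes.

    Expected columns: sample, group, gene, ct_target, ct_reference.
    """
    missing = [c for c in _CT_COLUMNS if c not in ct_frame.columns]
    if missing:
        raise SchemaError(f"Ct table missing columns {missing}")
    genes, folds, raw_p = [], [], []
    for gene, sub in ct_frame.groupby("gene", sort=True):
        samples = [
            QpcrSample(
                sample=str(r.sample), group=str(r.group),
                ct_target=float(r.ct_target), ct_reference=float(r.ct_reference),
            )
            for r in sub.itertuples()
        ]
        res = ddct_fold(samples, scale=scale)
        genes.append(gene)
        folds.append(res.fold_change)
        raw_p.append(res.p)
    adjusted, reject = holm_sidak(raw_p, alpha=alpha)
    frame = pd.DataFrame(
        {
            "gene": genes,
            "fold_change": folds,
            "p": raw_p,
            "p_holm_sidak": adjusted,
            "significant": reject,
        }
    )
    return ResultTable(frame=frame, metadata={"alpha": alpha, "test_scale": scale})
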