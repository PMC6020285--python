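"""Cross-experiment concordance: orientation, intersection, classification
and fold-change rank-sum prioritization.

The central assumption is biological: a gene truly controlled by the
pathway responds with the *same sign* in both experiments once both fold
changes are oriented so that positive regulation appears as fc > 1 (e.g.
the inhibitor-arm fold change is reported vehicle/inhibitor). Genes
significant in both arms are classified concordant-positive (both fc > 1),
concordant-negative (both fc < 1) or discordant; discordant genes are
flagged and kept, never silently dropped. Within each concordant sign
class, genes are ranked by fold-change strength independently in each
experiment (rank 1 = largest fc for positives, smallest fc for negatives;
ties get average ranks) and prioritized by the sum of the two ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .diffexpr import DETable, UP, DOWN, FLAT
from .io import ResultTable

__all__ = [
    "ConcordantGene",
    "orient",
    "intersect_common",
    "classify",
    "rank_concordant",
    "concordance_table",
    "as_detections",
    "CONCORDANT_POSITIVE",
    "CONCORDANT_NEGATIVE",
    "DISCORDANT",
]

CONCORDANT_POSITIVE = "concordant_positive"
CONCORDANT_NEGATIVE = "concordant_negative"
DISCORDANT = "discordant"

_SWAP = {UP: DOWN, DOWN: UP, FLAT: FLAT}


@dataclass
class ConcordantGene:
    """One common gene with both oriented fold changes and its class.

    Ranks are populated by :func:`rank_concordant` for concordant genes
    only; ``rank_sum = rank_vitro + rank_vivo`` (>= 2, lower = stronger
    joint regulation).
    """

    gene: str
    fc_vitro: float
    fdr_vitro: float
    fc_vivo: float
    fdr_vivo: float
    klass: str
    rank_vitro: float | None = None
    rank_vivo: float | None = None
    rank_sum: float | None = None


def orient(table: DETable, flip: bool = True) -> DETable:
    """Re-orient a DE table by taking the reciprocal of every fold change.

    Flipping maps fc → 1/fc, negates log2fc, swaps condition means and
    numerator/denominator labels, and swaps up/down directions; p and fdr
    are untouched. With ``flip=False`` the table is returned as a copy.
    Used to report the inhibitor-arm comparison as vehicle/inhibitor so
    positively regulated genes appear upregulated in both experiments.
    """
    frame = table.frame.copy()
    if not flip:
        return DETable(table.comparison, table.numerator, table.denominator, frame)
    frame["fc"] = 1.0 / frame["fc"]
    frame["log2fc"] = -frame["log2fc"]
    frame[["mean_a", "mean_b"]] = frame[["mean_b", "mean_a"]].to_numpy()
    frame["direction"] = frame["direction"].map(_SWAP)
    return DETable(
        comparison=f"{table.denominator}_vs_{table.numerator}",
        numerator=table.denominator,
        denominator=table.numerator,
        frame=frame,
    )


def intersect_common(
    sig_a: set[tuple[str, str]], sig_b: set[tuple[str, str]]
) -> list[str]:
    """Genes significant in both experiments, regardless of direction.

    Returned sorted alphabetically.
    """
    genes_a = {g for g, _ in sig_a}
    genes_b = {g for g, _ in sig_b}
    return sorted(genes_a & genes_b)


def classify(
    common: list[str], table_vitro: DETable, table_vivo_oriented: DETable
) -> list[ConcordantGene]:
    """Classify each common gene by the signs of its oriented fold changes.

    Both tables must already be oriented so positive regulation means
    fc > 1. Genes with a flat fold change in either table cannot carry a
    sign and fall into the discordant class.
    """
    fv = table_vitro.frame
    fw = table_vivo_oriented.frame
    out: list[ConcordantGene] = []
    for gene in common:
        if gene not in fv.index:
            raise ValidationError(f"gene '{gene}' missing from in vitro DE table")
        if gene not in fw.index:
            raise ValidationError(f"gene '{gene}' missing from in vivo DE table")
        fc_vitro = float(fv.loc[gene, "fc"])
        fc_vivo = float(fw.loc[gene, "fc"])
        if fc_vitro > 1 and fc_vivo > 1:
            klass = CONCORDANT_POSITIVE
        elif fc_vitro < 1 and fc_vivo < 1:
            klass = CONCORDANT_NEGATIVE
        else:
            klass = DISCORDANT
        out.append(
            ConcordantGene(
                gene=gene,
                fc_vitro=fc_vitro,
                fdr_vitro=float(fv.loc[gene, "fdr"]),
                fc_vivo=fc_vivo,
                fdr_vivo=float(fw.loc[gene, "fdr"]),
                klass=klass,
            )
        )
    return out


_RANK_COLUMNS = [
    "rank",
    "gene",
    "fc_vitro",
    "fdr_vitro",
    "fc_vivo",
    "fdr_vivo",
    "rank_vitro",
    "rank_vivo",
    "rank_sum",
]


def rank_concordant(genes: list[ConcordantGene], top_k: int = 0) -> ResultTable:
    """Rank one concordant sign class by fold-change rank sum.

    Rank 1 is the largest fold change for the positive class and the
    smallest (strongest repression) for the negative class, assigned
    independently in each experiment with average ranks for ties. Output
    is sorted by ascending rank sum, ties broken by smaller in vitro FDR,
    then alphabetically; ``top_k`` rows are returned (all when 0).
    Mixing sign classes (or passing discordant genes) is an error.
    """
    if top_k < 0:
        raise ValidationError("top_k must be >= 0")
    if not genes:
        return ResultTable(frame=pd.DataFrame(columns=_RANK_COLUMNS), metadata={"n_input": 0})
    klasses = {g.klass for g in genes}
    if len(klasses) > 1:
        raise ValidationError(f"mixed sign classes in rank input: {sorted(klasses)}")
    klass = klasses.pop()
    if klass == DISCORDANT:
        raise ValidationError("discordant genes cannot be ranked")

    fc_vitro = np.array([g.fc_vitro for g in genes])
    fc_vivo = np.array([g.fc_vivo for g in genes])
    sign = -1.0 if klass == CONCORDANT_POSITIVE else 1.0
    rank_vitro = rankdata(sign * fc_vitro, method="average")
    rank_vivo = rankdata(sign * fc_vivo, method="average")

    frame = pd.DataFrame(
        {
            "gene": [g.gene for g in genes],
            "fc_vitro": fc_vitro,
            "fdr_vitro": [g.fdr_vitro for g in genes],
            "fc_vivo": fc_vivo,
            "fdr_vivo": [g.fdr_vivo for g in genes],
            "rank_vitro": rank_vitro,
            "rank_vivo": rank_vivo,
            "rank_sum": rank_vitro + rank_vivo,
        }
    )
    for g, rv, rw in zip(genes, rank_vitro, rank_vivo):
        g.rank_vitro, g.rank_vivo, g.rank_sum = float(rv), float(rw), float(rv + rw)
    frame = frame.sort_values(
        ["rank_sum", "fdr_vitro", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    if top_k:
        frame = frame.head(top_k)
    return ResultTable(
        frame=frame[_RANK_COLUMNS],
        metadata={"klass": klass, "n_input": len(genes), "top_k": top_k},
    )


def concordance_table(genes: list[ConcordantGene], **metadata) -> ResultTable:
    """All common genes with their class (discordant included), as a table."""
    frame = pd.DataFrame(
        {
            "gene": [g.gene for g in genes],
            "fc_vitro": [g.fc_vitro for g in genes],
            "fdr_vitro": [g.fdr_vitro for g in genes],
            "fc_vivo": [g.fc_vivo for g in genes],
            "fdr_vivo": [g.fdr_vivo for g in genes],
            "klass": [g.klass for g in genes],
        }
    )
    counts = frame["klass"].value_counts().to_dict() if len(frame) else {}
    meta = {
        "n_common": len(genes),
        "n_concordant_up": int(counts.get(CONCORDANT_POSITIVE, 0)),
        "n_concordant_down": int(counts.get(CONCORDANT_NEGATIVE, 0)),
        "n_discordant": int(counts.get(DISCORDANT, 0)),
        **metadata,
    }
    return ResultTable(frame=frame, metadata=meta)


def as_detections(genes: list[ConcordantGene]) -> set[tuple[str, str]]:
    """Concordant genes as (gene, positive|negative) detection pairs."""
    out = set()
    for g in genes:
        if g.klass == CONCORDANT_POSITIVE:
            out.add((g.gene, "positive"))
        elif g.klass == CONCORDANT_NEGATIVE:
            out.add((g.gene, "negative"))
    return out
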