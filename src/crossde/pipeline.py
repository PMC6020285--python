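"""End-to-end orchestration of the two-arm concordance analysis.

The analysis graph: per-arm differential expression → asymmetric FDR
gating (a stringent threshold on the robust arm, a permissive one on the
attenuated arm) → orientation of the second arm → intersection of
significant genes → sign-concordance classification → per-class fold-change
rank-sum prioritization → optional category over-representation of the
concordant set. Every intermediate is written as TSV with a metadata
header and the summary as versioned JSON, so a fixed config + seed is
byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import concord, diffexpr
from .enrich import enrich as run_enrichment
from .errors import SchemaError, StageError, ValidationError
from .io import (
    ExpressionMatrix,
    GeneSetCategory,
    ResultTable,
    read_expression_matrix,
    read_gene_sets,
    write_expression_matrix,
    write_table,
)
from .simulate import SimConfig, simulate_pair, score_recovery

__all__ = [
    "PipelineConfig",
    "SummaryReport",
    "VerificationReport",
    "run_pipeline",
    "verify_against_supplementary",
    "REPORT_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run.

    Either the four matrix/design paths are given, or ``sim`` holds a
    generator config (in which case the pipeline seed overrides the
    generator seed so one integer controls the whole run).
    """

    vitro_matrix: str | None = None
    vitro_design: str | None = None
    vivo_matrix: str | None = None
    vivo_design: str | None = None
    sim: SimConfig | None = None
    vitro_numerator: str = "SHH"
    vitro_denominator: str = "Veh"
    vivo_numerator: str = "Cyc"
    vivo_denominator: str = "Veh"
    alpha_vitro: float = 0.01
    alpha_vivo: float = 0.75
    flip_vivo: bool = True
    top_k: int = 30
    gene_sets: str | None = None
    background: str = "measured_both"
    method: str = "welch_t"
    case_fold: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_vitro", "alpha_vivo"):
            a = getattr(self, name)
            if not (0 < a <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {a}")
        have_paths = all(
            getattr(self, f) is not None
            for f in ("vitro_matrix", "vitro_design", "vivo_matrix", "vivo_design")
        )
        if self.sim is None and not have_paths:
            raise ValidationError(
                "config needs either all four matrix/design paths or a 'sim' block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw, sim=SimConfig.from_dict(sim) if sim is not None else None)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class SummaryReport:
    """Machine-readable run summary (counts are integers by construction)."""

    n_genes_vitro: int
    n_genes_vivo: int
    n_sig_a: int
    n_up_a: int
    n_down_a: int
    n_sig_b: int
    n_up_b: int
    n_down_b: int
    n_common: int
    n_concordant: int
    n_concordant_up: int
    n_concordant_down: int
    n_discordant: int
    enrichment: list[dict] = field(default_factory=list)
    top_positive: list[dict] = field(default_factory=list)
    top_negative: list[dict] = field(default_factory=list)
    recovery: dict | None = None
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def _load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, "object | None"]:
    if config.sim is not None:
        sim_cfg = SimConfig(**{**config.sim.to_dict(), "seed": config.seed})
        vitro, vivo, truth = simulate_pair(sim_cfg)
        return vitro, vivo, truth
    vitro = read_expression_matrix(
        config.vitro_matrix, config.vitro_design, case_fold=config.case_fold
    )
    vivo = read_expression_matrix(
        config.vivo_matrix, config.vivo_design, case_fold=config.case_fold
    )
    return vitro, vivo, None


def run_pipeline(config: PipelineConfig, out_dir) -> SummaryReport:
    """Execute the full concordance analysis and write all outputs.

    Writes per-arm DE tables, the oriented attenuated-arm table, the
    common-gene list, the classified concordance table, top-k ranked
    tables per sign class, optional enrichment results, and report.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load_inputs"):
        vitro, vivo, truth = _load_inputs(config)
        if config.sim is not None:
            write_expression_matrix(vitro, out / "vitro.tsv", out / "vitro_design.tsv")
            write_expression_matrix(vivo, out / "vivo.tsv", out / "vivo_design.tsv")
            tf = truth.frame.reset_index()
            write_table(
                ResultTable(frame=tf, metadata={"seed": config.seed}),
                out / "truth.tsv",
            )

    with _stage("de_vitro"):
        design_a = diffexpr.make_design(vitro, config.vitro_numerator, config.vitro_denominator)
        de_a = diffexpr.de_test(vitro, design_a, method=config.method)
        write_table(
            diffexpr.de_result_table(de_a, alpha=config.alpha_vitro, seed=config.seed),
            out / "de_vitro.tsv",
        )
    with _stage("de_vivo"):
        design_b = diffexpr.make_design(vivo, config.vivo_numerator, config.vivo_denominator)
        de_b = diffexpr.de_test(vivo, design_b, method=config.method)
        write_table(
            diffexpr.de_result_table(de_b, alpha=config.alpha_vivo, seed=config.seed),
            out / "de_vivo.tsv",
        )

    with _stage("significant"):
        sig_a = diffexpr.significant(de_a, config.alpha_vitro)
        sig_b = diffexpr.significant(de_b, config.alpha_vivo)

    with _stage("orient"):
        de_b_oriented = concord.orient(de_b, flip=config.flip_vivo)
        sig_b_oriented = {(g, d) for g, d in sig_b}
        if config.flip_vivo:
            swap = {"up": "down", "down": "up"}
            sig_b_oriented = {(g, swap[d]) for g, d in sig_b}
        write_table(
            diffexpr.de_result_table(de_b_oriented, alpha=config.alpha_vivo, seed=config.seed),
            out / "de_vivo_oriented.tsv",
        )

    with _stage("intersect"):
        common = concord.intersect_common(sig_a, sig_b_oriented)
        (out / "common_genes.txt").write_text("".join(g + "\n" for g in common))

    with _stage("classify"):
        classified = concord.classify(common, de_a, de_b_oriented)
        conc_table = concord.concordance_table(
            classified,
            alpha_vitro=config.alpha_vitro,
            alpha_vivo=config.alpha_vivo,
            seed=config.seed,
        )
        write_table(conc_table, out / "concordant.tsv")

    with _stage("rank"):
        positives = [g for g in classified if g.klass == concord.CONCORDANT_POSITIVE]
        negatives = [g for g in classified if g.klass == concord.CONCORDANT_NEGATIVE]
        top_pos = concord.rank_concordant(positives, top_k=config.top_k)
        top_neg = concord.rank_concordant(negatives, top_k=config.top_k)
        write_table(top_pos, out / "top_positive.tsv")
        write_table(top_neg, out / "top_negative.tsv")

    enrichment_results: list[dict] = []
    if config.gene_sets is not None:
        with _stage("enrich"):
            categories = read_gene_sets(config.gene_sets, case_fold=config.case_fold)
            background = set(vitro.gene_ids) & set(vivo.gene_ids)
            query = {
                g.gene
                for g in classified
                if g.klass in (concord.CONCORDANT_POSITIVE, concord.CONCORDANT_NEGATIVE)
            }
            logger.info(
                "enrichment background: %d genes measured in both arms", len(background)
            )
            results = run_enrichment(query, categories, background)
            enrichment_results = [
                {
                    "category": r.category,
                    "N": r.N,
                    "K": r.K,
                    "n": r.n,
                    "k": r.k,
                    "fold_enrichment": r.fold_enrichment,
                    "p": r.p,
                    "overlap_genes": list(r.overlap_genes),
                }
                for r in results
            ]
            write_table(
                ResultTable(
                    frame=pd.DataFrame(
                        [{k: v for k, v in row.items() if k != "overlap_genes"}
                         for row in enrichment_results]
                    ),
                    metadata={"background_size": len(background), "seed": config.seed},
                ),
                out / "enrichment.tsv",
            )

    recovery = None
    if truth is not None:
        with _stage("score_recovery"):
            counts = score_recovery(concord.as_detections(classified), truth)
            recovery = {
                "true_positive": counts.true_positive,
                "false_positive": counts.false_positive,
                "false_negative": counts.false_negative,
                "true_negative": counts.true_negative,
                "recall": counts.recall,
                "precision": counts.precision,
            }

    def _count(sig, d):
        return sum(1 for _, dd in sig if dd == d)

    report = SummaryReport(
        n_genes_vitro=len(vitro.gene_ids),
        n_genes_vivo=len(vivo.gene_ids),
        n_sig_a=len(sig_a),
        n_up_a=_count(sig_a, "up"),
        n_down_a=_count(sig_a, "down"),
        n_sig_b=len(sig_b),
        n_up_b=_count(sig_b, "up"),
        n_down_b=_count(sig_b, "down"),
        n_common=len(common),
        n_concordant=len(positives) + len(negatives),
        n_concordant_up=len(positives),
        n_concordant_down=len(negatives),
        n_discordant=sum(1 for g in classified if g.klass == concord.DISCORDANT),
        enrichment=enrichment_results,
        top_positive=top_pos.frame.to_dict(orient="records"),
        top_negative=top_neg.frame.to_dict(orient="records"),
        recovery=recovery,
        thresholds={
            "alpha_vitro": config.alpha_vitro,
            "alpha_vivo": config.alpha_vivo,
            "flip_vivo": config.flip_vivo,
            "top_k": config.top_k,
            "method": config.method,
        },
        seed=config.seed,
    )
    (out / "report.json").write_text(report.to_json() + "\n")
    return report


@dataclass
class VerificationReport:
    """Counts recomputed from an externally supplied common-gene table."""

    n_rows: int
    n_concordant: int
    n_concordant_up: int
    n_concordant_down: int
    n_discordant: int
    category_overlap: int | None = None
    category_overlap_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def verify_against_supplementary(
    common_table,
    ofc_category: GeneSetCategory | None = None,
    gene_col: str = "gene",
    fc_vitro_col: str = "fc_vitro",
    fc_vivo_col: str = "fc_vivo",
) -> VerificationReport:
    """Re-derive concordance counts from a common-gene fold-change table.

    The table (TSV, ``#`` comments allowed) must carry the gene symbol and
    both oriented fold-change columns; classification is re-applied from
    fold-change signs alone. If a category is supplied, its overlap with
    the concordant genes is reported.
    """
    df = pd.read_csv(common_table, sep="\t", comment="#")
    missing = [c for c in (gene_col, fc_vitro_col, fc_vivo_col) if c not in df.columns]
    if missing:
        raise SchemaError(f"{common_table}: missing required columns {missing}")
    fcv = df[fc_vitro_col].astype(float)
    fcw = df[fc_vivo_col].astype(float)
    up = (fcv > 1) & (fcw > 1)
    down = (fcv < 1) & (fcw < 1)
    concordant_genes = set(df.loc[up | down, gene_col].astype(str))
    report = VerificationReport(
        n_rows=len(df),
        n_concordant=int((up | down).sum()),
        n_concordant_up=int(up.sum()),
        n_concordant_down=int(down.sum()),
        n_discordant=int(len(df) - (up | down).sum()),
    )
    if ofc_category is not None:
        overlap = sorted(concordant_genes & ofc_category.member_set)
        report.category_overlap = len(overlap)
        report.category_overlap_genes = overlap
    return report
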