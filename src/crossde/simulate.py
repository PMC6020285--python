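"""Paired synthetic experiments with known regulated-gene truth.

The generator emulates the two-arm study design the pipeline is built for:

* an *in vitro* arm (ligand-stimulated cells vs vehicle, default 4 vs 4
  replicates) with robust fold changes, and
* an *in vivo* arm (vehicle vs pathway-inhibitor exposure, default 6 vs 6)
  in which the same truly regulated genes respond with strongly attenuated
  effects of the same sign once the inhibitor comparison is oriented as
  vehicle/inhibitor.

Intensities are log-normal: per-gene baselines and per-sample noise are
Gaussian on the log2 scale and emitted as ``2**log2signal``. Effect
magnitudes are truncated-normal (at zero), signed by each gene's regulation
status, and carried into the in vivo arm through a single attenuation
multiplier. One seeded generator governs every draw, in a fixed documented
order, so identical configs are bit-identical.

Draw order: baselines → status permutation → effect magnitudes (positives
then negatives, each in ascending gene-index order) → in vitro noise matrix
(treated columns then vehicle columns) → in vivo noise matrix (vehicle then
inhibitor columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "ConfusionCounts",
    "simulate_pair",
    "score_recovery",
    "POSITIVE",
    "NEGATIVE",
    "NULL",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NULL = "null"

#: condition labels used in the emitted designs
VITRO_TREATED, VITRO_CONTROL = "SHH", "Veh"
VIVO_CONTROL, VIVO_TREATED = "Veh", "Cyc"


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions of the design
    the package targets (4v4 robust in vitro arm, 6v6 attenuated in vivo
    arm, 2%+2% truly regulated genes)."""

    n_genes: int = 10_000
    frac_positive: float = 0.02
    frac_negative: float = 0.02
    effect_log2_mean: float = 2.0
    effect_log2_sd: float = 0.5
    attenuation: float = 0.25
    sigma_vitro: float = 0.25
    sigma_vivo: float = 0.5
    reps_vitro: int = 4
    reps_vivo: int = 6
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.reps_vitro < 2 or self.reps_vivo < 2:
            raise ValidationError("replicate counts must be >= 2")
        if not (0 <= self.frac_positive and 0 <= self.frac_negative):
            raise ValidationError("regulated fractions must be >= 0")
        if self.frac_positive + self.frac_negative > 1:
            raise ValidationError("frac_positive + frac_negative must be <= 1")
        if not (0 < self.attenuation <= 1):
            raise ValidationError("attenuation must lie in (0, 1]")
        for name in ("effect_log2_sd", "sigma_vitro", "sigma_vivo", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimTruth:
    """Per-gene ground truth: regulation status and oriented log2 effects.

    ``true_log2fc_vivo`` is oriented vehicle/inhibitor, so non-null genes
    share the sign of their in vitro effect.
    """

    frame: pd.DataFrame  # index gene; columns status, true_log2fc_vitro, true_log2fc_vivo

    @property
    def n_genes(self) -> int:
        return len(self.frame)

    @property
    def regulated(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] != NULL]

    def status_of(self, gene: str) -> str:
        return self.frame.loc[gene, "status"]

    def true_detections(self) -> set[tuple[str, str]]:
        """The (gene, direction) pairs a perfect detector would return."""
        reg = self.regulated
        return set(zip(reg.index, reg["status"]))


@dataclass
class ConfusionCounts:
    """Detection bookkeeping against simulation truth.

    A detection is a true positive only if the gene is truly regulated AND
    the detected direction matches its status; a wrong-sign call on a true
    gene therefore counts once as a false positive and leaves that gene a
    false negative. ``true_negative`` is defined as the remainder so the
    four counts always sum to ``n_genes``.
    """

    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int

    @property
    def n_genes(self) -> int:
        return self.true_positive + self.false_positive + self.false_negative + self.true_negative

    @property
    def recall(self) -> float:
        denom = self.true_positive + self.false_negative
        return self.true_positive / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.true_positive + self.false_positive
        return self.true_positive / denom if denom else 0.0


def _truncated_normal(rng, mean, sd, size) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0 (exact, not folded)."""
    if sd == 0:
        if mean < 0:
            raise ValidationError("degenerate effect distribution below truncation")
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_pair(config: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Generate the paired in vitro / in vivo matrices and their truth.

    In vitro samples: treated = baseline + effect + noise, control =
    baseline + noise. In vivo samples: vehicle = baseline + noise,
    inhibitor = baseline − attenuation·effect + noise (so the
    vehicle/inhibitor orientation recovers the in vitro sign). All on the
    log2 scale; intensities are ``2**log2signal``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = [f"G{i:06d}" for i in range(1, n + 1)]

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)

    n_pos = int(round(cfg.frac_positive * n))
    n_neg = int(round(cfg.frac_negative * n))
    if n_pos + n_neg > n:
        raise ValidationError("rounded regulated counts exceed n_genes")
    perm = rng.permutation(n)
    pos_idx = np.sort(perm[:n_pos])
    neg_idx = np.sort(perm[n_pos : n_pos + n_neg])

    effect = np.zeros(n)
    effect[pos_idx] = _truncated_normal(rng, cfg.effect_log2_mean, cfg.effect_log2_sd, n_pos)
    effect[neg_idx] = -_truncated_normal(rng, cfg.effect_log2_mean, cfg.effect_log2_sd, n_neg)

    rv, rw = cfg.reps_vitro, cfg.reps_vivo
    noise_vitro = rng.normal(0.0, cfg.sigma_vitro, (n, 2 * rv)) if cfg.sigma_vitro > 0 else np.zeros((n, 2 * rv))
    noise_vivo = rng.normal(0.0, cfg.sigma_vivo, (n, 2 * rw)) if cfg.sigma_vivo > 0 else np.zeros((n, 2 * rw))

    log2_vitro = np.empty((n, 2 * rv))
    log2_vitro[:, :rv] = baseline[:, None] + effect[:, None] + noise_vitro[:, :rv]
    log2_vitro[:, rv:] = baseline[:, None] + noise_vitro[:, rv:]

    log2_vivo = np.empty((n, 2 * rw))
    log2_vivo[:, :rw] = baseline[:, None] + noise_vivo[:, :rw]
    log2_vivo[:, rw:] = baseline[:, None] - cfg.attenuation * effect[:, None] + noise_vivo[:, rw:]

    vitro_samples = [f"{VITRO_TREATED}_{i}" for i in range(1, rv + 1)] + [
        f"{VITRO_CONTROL}_{i}" for i in range(1, rv + 1)
    ]
    vivo_samples = [f"{VIVO_CONTROL}_{i}" for i in range(1, rw + 1)] + [
        f"{VIVO_TREATED}_{i}" for i in range(1, rw + 1)
    ]
    vitro = ExpressionMatrix(
        values=pd.DataFrame(np.exp2(log2_vitro), index=genes, columns=vitro_samples),
        design={s: (VITRO_TREATED if s.startswith(VITRO_TREATED) else VITRO_CONTROL) for s in vitro_samples},
    )
    vivo = ExpressionMatrix(
        values=pd.DataFrame(np.exp2(log2_vivo), index=genes, columns=vivo_samples),
        design={s: (VIVO_TREATED if s.startswith(VIVO_TREATED) else VIVO_CONTROL) for s in vivo_samples},
    )

    status = np.full(n, NULL, dtype=object)
    status[pos_idx] = POSITIVE
    status[neg_idx] = NEGATIVE
    truth = SimTruth(
        frame=pd.DataFrame(
            {
                "status": status,
                "true_log2fc_vitro": effect,
                "true_log2fc_vivo": cfg.attenuation * effect,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    return vitro, vivo, truth


_DIRECTION_ALIASES = {"up": POSITIVE, "down": NEGATIVE, POSITIVE: POSITIVE, NEGATIVE: NEGATIVE}


def score_recovery(detected: set[tuple[str, str]], truth: SimTruth) -> ConfusionCounts:
    """Confront a set of (gene, direction) calls with the simulation truth.

    Directions may be given as positive/negative or up/down (the oriented
    pipeline vocabulary).
    """
    frame = truth.frame
    tp = fp = 0
    for gene, direction in detected:
        if gene not in frame.index:
            raise ValidationError(f"detected gene '{gene}' not present in truth")
        if direction not in _DIRECTION_ALIASES:
            raise ValidationError(f"unknown detection direction '{direction}'")
        if frame.loc[gene, "status"] == _DIRECTION_ALIASES[direction]:
            tp += 1
        else:
            fp += 1
    n_regulated = int((frame["status"] != NULL).sum())
    fn = n_regulated - tp
    tn = truth.n_genes - tp - fp - fn
    return ConfusionCounts(true_positive=tp, false_positive=fp, false_negative=fn, true_negative=tn)
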