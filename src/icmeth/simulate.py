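"""Synthetic cohort, methylome, expression and survival generator.

Produces data with the statistical structure the downstream analyses
assume — flat-then-declining domain trajectories with sex offsets,
CpGs logistically coupled to the IC score, cell-mixture-driven CpGs with
age-trending composition, expression coupled to age-adjusted IC, and
proportional-hazards survival — together with ground-truth labels for
recovery tests. One global seed; each stage draws from its own
deterministic substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError
from .score import INSTRUMENTS, RAW_COLUMNS

__all__ = [
    "DomainTrajectory",
    "SurvivalConfig",
    "SimulationConfig",
    "default_config",
    "simulate_cohort",
    "make_reference",
    "simulate_methylome",
    "simulate_expression",
    "simulate_survival",
]

# fixed substream keys so stages are independent and reproducible
_STREAM = {"cohort": 1, "reference": 2, "methylome": 3, "expression": 4, "survival": 5}

CELL_TYPES = ["CD8T", "CD4T", "NK", "B", "granulocyte", "monocyte"]


@dataclass(frozen=True)
class DomainTrajectory:
    """Flat-before-breakpoint, linear-after trajectory for one instrument."""

    baseline: float
    breakpoint_age: float
    post_slope: float
    sex_offset: float = 0.0  # added for males
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SurvivalConfig:
    baseline_rate: float = 0.02  # events / year
    log_hr_per_sd: float = 0.3
    censor_rate: float = 0.01
    horizon: float = 25.0


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 500
    age_range: tuple[float, float] = (20.0, 102.0)
    seed: int = 0
    domains: dict[str, DomainTrajectory] = field(default_factory=dict)
    n_cpgs: int = 2000
    n_causal_cpgs: int = 10
    causal_effect_sd: float = 2.0  # logit-beta units per IC unit
    beta_noise_sd: float = 0.02
    n_celltype_cpgs: int = 100
    n_genes: int = 1000
    n_ic_genes: int = 50
    expression_effect_sd: float = 1.0  # log-expression per unit predictor
    expression_noise_sd: float = 1.0
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must be increasing")
        if self.n_causal_cpgs + self.n_celltype_cpgs > self.n_cpgs:
            raise ConfigurationError("causal + cell-type CpGs exceed n_cpgs")
        if self.n_ic_genes > self.n_genes:
            raise ConfigurationError("n_ic_genes exceeds n_genes")
        for name in ("causal_effect_sd", "beta_noise_sd", "expression_effect_sd",
                     "expression_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name, tr in self.domains.items():
            if tr.noise_sd < 0:
                raise ConfigurationError(f"domain {name}: noise_sd must be >= 0")
        s = self.survival
        if s.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be positive")
        if s.censor_rate < 0 or s.horizon <= 0:
            raise ConfigurationError("invalid censoring configuration")


def _default_domains() -> dict[str, DomainTrajectory]:
    return {
        "mmse": DomainTrajectory(29.0, 70.0, -0.18, 0.0, 1.0),
        "sppb": DomainTrajectory(12.0, 62.0, -0.10, 0.0, 0.8),
        # PHQ-9 is higher-is-worse: depressive symptoms rise after midlife,
        # males report slightly fewer
        "phq9": DomainTrajectory(3.0, 55.0, 0.10, -1.0, 1.5),
        "vision": DomainTrajectory(3.0, 55.0, -0.025, 0.0, 0.3),
        "hearing": DomainTrajectory(2.0, 60.0, -0.02, 0.0, 0.25),
        "grip": DomainTrajectory(42.0, 50.0, -0.35, 10.0, 4.0),
    }


def default_config(**overrides) -> SimulationConfig:
    """A lifespan-cohort configuration with age-declining domain scores."""
    cfg = SimulationConfig(domains=_default_domains())
    return replace(cfg, **overrides) if overrides else cfg


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[stage]])


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the participant table: age, sex and six raw instrument scores.

    Each raw score is flat at its baseline before the breakpoint age, then
    declines (or rises, for higher-is-worse instruments) linearly, with an
    additive male sex offset and Gaussian noise, clipped to the declared
    instrument bounds.
    """
    if set(config.domains) != set(RAW_COLUMNS):
        raise ConfigurationError(
            f"config.domains must define exactly {RAW_COLUMNS}"
        )
    rng = _rng(config, "cohort")
    n = config.n_participants
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    male = rng.random(n) < 0.5
    data = {
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": np.where(male, "male", "female"),
    }
    for name in RAW_COLUMNS:
        tr = config.domains[name]
        raw = (
            tr.baseline
            + tr.post_slope * np.maximum(0.0, age - tr.breakpoint_age)
            + tr.sex_offset * male
            + rng.normal(0.0, tr.noise_sd, size=n) * (tr.noise_sd > 0)
        )
        spec = INSTRUMENTS[name]
        lo_b = spec.lo if spec.lo is not None else 0.0  # grip floors at 0 kg
        raw = np.clip(raw, lo_b, spec.hi if spec.hi is not None else np.inf)
        data[name] = raw
    return pd.DataFrame(data).set_index("participant_id")


def make_reference(config: SimulationConfig) -> pd.DataFrame:
    """Cell-type reference: per-CpG mean betas for the six leukocyte types,
    drawn to be discriminating, over the cell-type CpG block."""
    rng = _rng(config, "reference")
    ids = [f"cg_ct{i:05d}" for i in range(config.n_celltype_cpgs)]
    vals = rng.uniform(0.05, 0.95, size=(config.n_celltype_cpgs, len(CELL_TYPES)))
    return pd.DataFrame(vals, index=ids, columns=CELL_TYPES)


def _age_trending_proportions(age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Convex mixing weights per sample; granulocytes rise and CD4/CD8/NK
    shrink with age (softmax of linear-in-age scores plus noise)."""
    slopes = np.array([-0.6, -0.8, -0.3, -0.2, 1.0, 0.2])  # per CELL_TYPES
    base = np.array([0.1, 0.9, -0.3, -0.4, 1.2, 0.0])
    a = (age - 60.0) / 40.0
    logits = base + slopes * a[:, None] + rng.normal(0, 0.15, size=(age.size, len(slopes)))
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def simulate_methylome(
    cohort: pd.DataFrame,
    ic: pd.Series,
    config: SimulationConfig,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a CpG x sample beta matrix with planted structure.

    Three CpG blocks: causal CpGs whose mean beta is
    ``logistic(b0 + b1*IC)`` with b1 ~ N(0, causal_effect_sd); cell-type
    CpGs that are convex mixtures of the reference profiles with
    age-trending weights; and IC-independent noise CpGs. Gaussian noise
    (``beta_noise_sd``) is added everywhere and values clipped to [0, 1].

    Returns the beta matrix and a ground-truth dict with the causal CpG
    coefficients, the reference and the true mixing proportions.
    """
    if not cohort.index.equals(ic.index):
        raise AlignmentError("ic must be aligned to the cohort index")
    rng = _rng(config, "methylome")
    n = len(cohort)
    if reference is None:
        reference = make_reference(config)
    ic_v = ic.to_numpy(dtype=float)

    n_causal, n_ct = config.n_causal_cpgs, config.n_celltype_cpgs
    n_noise = config.n_cpgs - n_causal - n_ct

    b0 = rng.normal(0.0, 1.0, size=n_causal)
    # effect magnitudes bounded away from zero (uniform on +/-[0.5, 1.5]*sd)
    # so every planted CpG carries recoverable signal
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    b1 = signs * config.causal_effect_sd * rng.uniform(0.5, 1.5, size=n_causal)
    if config.causal_effect_sd == 0:
        b1 = np.zeros(n_causal)
    # dose-response centered at IC = 0.75 so the logistic stays off its
    # saturated tails over the realistic score range
    logits = b0[:, None] + b1[:, None] * (ic_v[None, :] - 0.75)
    b0 = b0 - 0.75 * b1  # report coefficients on the raw-IC scale
    causal = 1.0 / (1.0 + np.exp(-logits))

    props = _age_trending_proportions(cohort["age"].to_numpy(dtype=float), rng)
    celltype = reference.to_numpy(dtype=float) @ props.T

    noise_means = rng.uniform(0.05, 0.95, size=n_noise)
    noise = np.repeat(noise_means[:, None], n, axis=1)

    values = np.vstack([causal, celltype, noise])
    if config.beta_noise_sd > 0:
        values = values + rng.normal(0.0, config.beta_noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    causal_ids = [f"cg_ic{i:05d}" for i in range(n_causal)]
    noise_ids = [f"cg_bg{i:05d}" for i in range(n_noise)]
    ids = causal_ids + list(reference.index) + noise_ids
    betas = pd.DataFrame(values, index=ids, columns=cohort.index)
    truth = {
        "causal_cpgs": pd.DataFrame({"b0": b0, "b1": b1}, index=causal_ids),
        "reference": reference,
        "proportions": pd.DataFrame(props, index=cohort.index, columns=reference.columns),
    }
    return betas, truth


def simulate_expression(
    cohort: pd.DataFrame,
    ic_acceleration: pd.Series,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample expression: ``n_ic_genes`` genes linear in the
    age-adjusted IC predictor plus Gaussian noise, the rest pure noise.

    Returns the expression table and the ground-truth coefficient per gene
    (zero for null genes).
    """
    if not cohort.index.equals(ic_acceleration.index):
        raise AlignmentError("ic_acceleration must be aligned to the cohort index")
    rng = _rng(config, "expression")
    n = len(cohort)
    coefs = np.zeros(config.n_genes)
    # magnitudes bounded away from zero, as for the causal CpGs
    signs = rng.choice([-1.0, 1.0], size=config.n_ic_genes)
    coefs[: config.n_ic_genes] = (
        signs * config.expression_effect_sd * rng.uniform(0.5, 1.5, size=config.n_ic_genes)
    )
    pred = ic_acceleration.to_numpy(dtype=float)
    vals = coefs[:, None] * pred[None, :]
    if config.expression_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.expression_noise_sd, size=vals.shape)
    ids = [f"G{i:05d}" for i in range(config.n_genes)]
    expr = pd.DataFrame(vals, index=ids, columns=cohort.index)
    return expr, pd.Series(coefs, index=ids, name="true_coef")


def simulate_survival(
    cohort: pd.DataFrame, predictor: pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """Proportional-hazards event times with independent exponential and
    administrative censoring.

    Event times are exponential with rate
    ``baseline_rate * exp(log_hr_per_sd * predictor)``; the predictor is
    expected to be standardized. Returns columns ``survival_time, event``.
    """
    if not cohort.index.equals(predictor.index):
        raise AlignmentError("predictor must be aligned to the cohort index")
    s = config.survival
    rng = _rng(config, "survival")
    n = len(cohort)
    rate = s.baseline_rate * np.exp(s.log_hr_per_sd * predictor.to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / rate)
    if s.censor_rate > 0:
        t_cens = rng.exponential(1.0 / s.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, s.horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # survival times strictly positive
    return pd.DataFrame({"survival_time": time, "event": event}, index=cohort.index)
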