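"""Composite intrinsic-capacity (IC) scoring from five clinical domains.

The score is built in four steps: per-instrument rescaling to [0, 1]
(direction-corrected so higher is always better), averaging of the two
sensory instruments into one domain, per-domain z-transformation over the
cohort, and min-max normalization of the five-domain z-average so the
cohort spans exactly [0, 1]. Only complete cases (all five domains
observed) are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ContractError,
    DegenerateDomainError,
    NoCompleteCasesError,
    RangeError,
)

__all__ = [
    "DomainSpec",
    "INSTRUMENTS",
    "RAW_COLUMNS",
    "DOMAINS",
    "ScoringParams",
    "ICScoreResult",
    "complete_case_filter",
    "rescale_domain",
    "sensory_score",
    "zscore_domains",
    "overall_ic",
    "score_cohort",
    "apply_scoring",
]


@dataclass(frozen=True)
class DomainSpec:
    """Declared range and direction of one clinical instrument.

    ``lo``/``hi`` of ``None`` mean the instrument is unbounded and the
    observed cohort minimum/maximum define the rescaling bounds (grip
    strength is the only such instrument here).
    """

    name: str
    lo: float | None
    hi: float | None
    direction: str = "higher_better"  # or "higher_worse"

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "higher_worse"):
            raise ContractError(f"unknown direction {self.direction!r}")
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise ContractError(f"domain {self.name}: need lo < hi, got {self.lo}, {self.hi}")


#: The six clinical instruments feeding the five IC domains.
INSTRUMENTS: dict[str, DomainSpec] = {
    "mmse": DomainSpec("mmse", 0, 30),
    "sppb": DomainSpec("sppb", 0, 12),
    "phq9": DomainSpec("phq9", 0, 27, direction="higher_worse"),
    "vision": DomainSpec("vision", 0, 3),
    "hearing": DomainSpec("hearing", 0, 2),
    "grip": DomainSpec("grip", None, None),
}

RAW_COLUMNS = ["mmse", "sppb", "phq9", "vision", "hearing", "grip"]
DOMAINS = ["cognition", "locomotion", "psychological", "sensory", "vitality"]

_INSTRUMENT_TO_DOMAIN = {
    "mmse": "cognition",
    "sppb": "locomotion",
    "phq9": "psychological",
    "grip": "vitality",
}


@dataclass
class ScoringParams:
    """Frozen transform parameters so the same scoring can be reapplied."""

    unbounded_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    domain_means: dict[str, float] = field(default_factory=dict)
    domain_sds: dict[str, float] = field(default_factory=dict)
    overall_min: float = 0.0
    overall_max: float = 1.0


@dataclass
class ICScoreResult:
    table: pd.DataFrame  # rescaled domains, z-scores, overall_ic
    params: ScoringParams
    n_removed: int  # incomplete cases dropped


def complete_case_filter(
    cohort: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Keep only participants observed on every instrument.

    Returns the filtered table and the number of rows removed.
    """
    columns = RAW_COLUMNS if columns is None else columns
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ContractError(f"cohort is missing instrument columns: {missing}")
    mask = cohort[columns].notna().all(axis=1)
    out = cohort.loc[mask]
    if out.empty:
        raise NoCompleteCasesError("no participant has all five domains observed")
    return out, int((~mask).sum())


def rescale_domain(
    raw, spec: DomainSpec, bounds: tuple[float, float] | None = None
) -> np.ndarray:
    """Rescale raw instrument scores to [0, 1], higher = better.

    Bounded instruments use their declared range; unbounded ones use
    ``bounds`` (or, if absent, the observed min/max of ``raw``).
    ``higher_worse`` instruments are reversed after rescaling.
    """
    x = np.asarray(raw, dtype=float)
    if spec.lo is not None and spec.hi is not None:
        lo, hi = float(spec.lo), float(spec.hi)
        finite = x[np.isfinite(x)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise RangeError(
                f"{spec.name}: raw values outside declared range [{lo}, {hi}]"
            )
    elif bounds is not None:
        lo, hi = map(float, bounds)
    else:
        finite = x[np.isfinite(x)]
        if finite.size == 0:
            raise DegenerateDomainError(f"{spec.name}: no observed values")
        lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise DegenerateDomainError(f"{spec.name}: degenerate bounds ({lo} == {hi})")
    u = (x - lo) / (hi - lo)
    if spec.direction == "higher_worse":
        u = 1.0 - u
    return u


def sensory_score(vision, hearing) -> np.ndarray:
    """Sensory domain = arithmetic mean of the rescaled vision and hearing scores."""
    v = np.asarray(vision, dtype=float)
    h = np.asarray(hearing, dtype=float)
    if v.shape != h.shape:
        raise ContractError("vision and hearing must have the same length")
    return (v + h) / 2.0


def zscore_domains(
    rescaled: pd.DataFrame,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Per-domain z-transform with sample sd (denominator n - 1).

    When ``means``/``sds`` are given they are applied as frozen
    parameters; otherwise they are estimated from ``rescaled``.
    """
    if means is None or sds is None:
        if len(rescaled) < 2:
            raise ContractError("z-transform needs at least two participants")
        means = {c: float(rescaled[c].mean()) for c in rescaled.columns}
        sds = {c: float(rescaled[c].std(ddof=1)) for c in rescaled.columns}
        for c, s in sds.items():
            if not np.isfinite(s) or s == 0:
                raise DegenerateDomainError(f"domain {c!r} has zero variance")
    z = (rescaled - pd.Series(means)) / pd.Series(sds)
    return z, means, sds


def overall_ic(
    z: pd.DataFrame, minmax: tuple[float, float] | None = None
) -> tuple[pd.Series, float, float]:
    """Average the five domain z-scores and min-max normalize to [0, 1]."""
    if z.shape[1] != 5:
        raise ContractError(f"expected five domain columns, got {z.shape[1]}")
    avg = z.mean(axis=1)
    if minmax is None:
        lo, hi = float(avg.min()), float(avg.max())
    else:
        lo, hi = minmax
    if hi == lo:
        raise DegenerateDomainError("overall score is constant; min-max undefined")
    return (avg - lo) / (hi - lo), lo, hi


def _rescaled_table(cohort: pd.DataFrame, params: ScoringParams, freeze: bool) -> pd.DataFrame:
    cols = {}
    for name, spec in INSTRUMENTS.items():
        bounds = None
        if spec.lo is None or spec.hi is None:
            if freeze:
                x = cohort[name].to_numpy(dtype=float)
                bounds = (float(np.nanmin(x)), float(np.nanmax(x)))
                params.unbounded_bounds[name] = bounds
            else:
                bounds = params.unbounded_bounds[name]
        cols[name] = rescale_domain(cohort[name], spec, bounds=bounds)
    out = pd.DataFrame(index=cohort.index)
    for instr, dom in _INSTRUMENT_TO_DOMAIN.items():
        out[dom] = cols[instr]
    out["sensory"] = sensory_score(cols["vision"], cols["hearing"])
    return out[DOMAINS]


def score_cohort(cohort: pd.DataFrame) -> ICScoreResult:
    """Full scoring pipeline on a cohort table with the six instrument columns.

    Applies complete-case filtering, rescaling, sensory averaging,
    z-transformation and min-max normalization; all transform parameters
    are frozen in the result so new individuals can be scored consistently
    with :func:`apply_scoring`.
    """
    complete, n_removed = complete_case_filter(cohort)
    params = ScoringParams()
    rescaled = _rescaled_table(complete, params, freeze=True)
    z, means, sds = zscore_domains(rescaled)
    params.domain_means, params.domain_sds = means, sds
    ic, lo, hi = overall_ic(z)
    params.overall_min, params.overall_max = lo, hi
    table = pd.concat(
        [rescaled, z.add_prefix("z_"), ic.rename("overall_ic")], axis=1
    )
    return ICScoreResult(table=table, params=params, n_removed=n_removed)


def apply_scoring(params: ScoringParams, cohort: pd.DataFrame) -> pd.DataFrame:
    """Score new individuals with frozen parameters (no re-estimation)."""
    complete, _ = complete_case_filter(cohort)
    rescaled = _rescaled_table(complete, params, freeze=False)
    z, _, _ = zscore_domains(rescaled, params.domain_means, params.domain_sds)
    ic, _, _ = overall_ic(z, minmax=(params.overall_min, params.overall_max))
    return pd.concat([rescaled, z.add_prefix("z_"), ic.rename("overall_ic")], axis=1)
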