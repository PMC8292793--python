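"""Norm-referenced Z scoring of a family's SRM ANOVA effects.

Each of the 21 per-family ANOVA scores is standardized against its
sampling distribution in the norm population: Z = (score - norm mean) /
norm sd.  Two-sided p-values use the standard normal reference (the norm
sample size is not an input, so no finite-sample correction is applied).
|Z| >= 2 flags an extreme deviation; |Z| >= 1 a potential risk factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import norm as _stdnorm

from .norms import SD_FLOOR, SRMPopulationParameters, sampling_distribution, validate_params
from .roundrobin import AnovaScores, RoundRobinData, ValidationError, decompose

__all__ = [
    "AssessConfig",
    "ReportRow",
    "AssessmentReport",
    "z_score",
    "p_value",
    "classify",
    "assess",
]

FLAG_TYPICAL = "typical"
FLAG_ELEVATED = "elevated"
FLAG_EXTREME = "extreme"
FLAG_NON_ASSESSABLE = "non_assessable"


@dataclass(frozen=True)
class AssessConfig:
    """Thresholds and options for the assessment report.

    ``adjust`` is ``"none"`` (raw p-values, the conventional report) or
    ``"holm"`` for an opt-in step-down multiplicity adjustment over the
    21 tests.
    """

    elevated: float = 1.0
    extreme: float = 2.0
    adjust: str = "none"

    def __post_init__(self) -> None:
        if not (0 < self.elevated < self.extreme):
            raise ValidationError(
                f"thresholds must satisfy 0 < elevated < extreme, got "
                f"elevated={self.elevated}, extreme={self.extreme}"
            )
        if self.adjust not in ("none", "holm"):
            raise ValidationError(f"adjust must be 'none' or 'holm', got {self.adjust!r}")


def z_score(anova: float, mean: float, sd: float) -> float:
    """Standardize one ANOVA score against its norm mean and sd.

    Returns NaN when sd is at or below the assessability floor; the
    report marks such effects non-assessable rather than raising.
    """
    if sd < SD_FLOOR:
        return math.nan
    return (anova - mean) / sd


def p_value(z: float) -> float:
    """Two-sided tail probability of z under the standard normal."""
    if math.isnan(z):
        return math.nan
    return float(2.0 * _stdnorm.sf(abs(z)))


def classify(z: float, elevated: float = 1.0, extreme: float = 2.0) -> str:
    """Map a Z score to a qualitative flag.

    extreme if |z| >= extreme threshold, elevated if in [elevated,
    extreme), typical below, non_assessable for NaN.
    """
    if not (0 < elevated < extreme):
        raise ValidationError(
            f"thresholds must satisfy 0 < elevated < extreme, got {elevated}, {extreme}"
        )
    if math.isnan(z):
        return FLAG_NON_ASSESSABLE
    a = abs(z)
    if a >= extreme:
        return FLAG_EXTREME
    if a >= elevated:
        return FLAG_ELEVATED
    return FLAG_TYPICAL


@dataclass(frozen=True)
class ReportRow:
    effect: str
    anova_score: float
    z: float
    p: float
    flag: str
    variance_significant: bool | None = None


@dataclass(frozen=True)
class AssessmentReport:
    """The 21-row family assessment plus provenance metadata."""

    rows: Sequence[ReportRow]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_dataframe(self, digits: int | None = 3) -> pd.DataFrame:
        """Tabular view; ``digits=None`` keeps full precision."""
        df = pd.DataFrame(
            {
                "effect": [r.effect for r in self.rows],
                "anova_score": [r.anova_score for r in self.rows],
                "z": [r.z for r in self.rows],
                "p": [r.p for r in self.rows],
                "flag": [r.flag for r in self.rows],
            }
        )
        if digits is not None:
            for c in ("anova_score", "z", "p"):
                df[c] = df[c].round(digits)
        return df

    def to_dict(self) -> dict:
        """JSON-ready representation at full precision."""
        return {
            "rows": [
                {
                    "effect": r.effect,
                    "anova_score": r.anova_score,
                    "z": None if math.isnan(r.z) else r.z,
                    "p": None if math.isnan(r.p) else r.p,
                    "flag": r.flag,
                    **(
                        {"variance_significant": r.variance_significant}
                        if r.variance_significant is not None
                        else {}
                    ),
                }
                for r in self.rows
            ],
            "metadata": dict(self.metadata),
        }

    def flagged(self) -> list[ReportRow]:
        return [r for r in self.rows if r.flag in (FLAG_ELEVATED, FLAG_EXTREME)]


def assess(
    data: RoundRobinData,
    params: SRMPopulationParameters,
    config: AssessConfig | None = None,
) -> AssessmentReport:
    """Run the full norm-referenced assessment for one family.

    Decomposes the round robin into ANOVA scores, derives the norm
    sampling distribution from the CFA parameters, and returns Z scores,
    two-sided p-values and flags for all 21 effects.  Roles of the data
    and the parameters must match (same labels, same order).
    """
    config = config or AssessConfig()
    if set(data.roles.labels) != set(params.roles.labels):
        raise ValidationError(
            f"role labels of data {data.roles.labels!r} and norm parameters "
            f"{params.roles.labels!r} do not match"
        )
    if data.roles.labels != params.roles.labels:
        # same roles, different input order: report in the norms' order so
        # results do not depend on the row order of the dyad file
        data = RoundRobinData(params.roles, dict(data.values))
    scores: AnovaScores = decompose(data)
    dist = sampling_distribution(params)
    score_map = scores.as_dict()

    zs = {e: z_score(score_map[e], dist.mean[e], dist.sd[e]) for e in score_map}
    ps = {e: p_value(z) for e, z in zs.items()}
    if config.adjust == "holm":
        ps = _holm(ps)

    sig = params.variance_significant
    rows = [
        ReportRow(
            effect=e,
            anova_score=score_map[e],
            z=zs[e],
            p=ps[e],
            flag=classify(zs[e], config.elevated, config.extreme),
            variance_significant=None if sig is None else sig.get(e),
        )
        for e in score_map
    ]

    warnings = [d.message for d in validate_params(params) if d.severity == "warning"]
    footnotes = []
    if sig is not None:
        unflagged = [e for e in score_map if not sig.get(e, False)]
        if unflagged:
            footnotes.append(
                "Z scores are only interpretable for effects with significant "
                "norm-sample variance; interpret with caution: " + ", ".join(unflagged)
            )
    meta = {
        "roles": list(data.roles.labels),
        "thresholds": {"elevated": config.elevated, "extreme": config.extreme},
        "p_adjustment": config.adjust,
        "reciprocity_scale": params.reciprocity_scale,
        "parameter_warnings": warnings,
        "non_assessable": list(dist.non_assessable),
        "footnotes": footnotes,
    }
    return AssessmentReport(rows=rows, metadata=meta)


def _holm(ps: Mapping[str, float]) -> dict[str, float]:
    """Holm step-down adjustment, passing NaNs through untouched."""
    from statsmodels.stats.multitest import multipletests

    keys = [k for k, v in ps.items() if not math.isnan(v)]
    if keys:
        _, adj, _, _ = multipletests([ps[k] for k in keys], method="holm")
        adjusted = dict(zip(keys, adj.tolist()))
    else:
        adjusted = {}
    return {k: adjusted.get(k, math.nan) for k in ps}
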