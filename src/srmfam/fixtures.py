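"""Bundled worked example: an attachment-anxiety family assessment.

The example is the textbook case used throughout the dyadic-data
literature: one randomly chosen two-parent, two-child US family whose
members rated relationship anxiety (RS-anxiety, mean of five 5-point
Likert items) toward each other member, assessed against a published
norm study of 208 comparable families.  The norm parameters are the
CFA estimates of the SRM means, variances and reciprocity correlations
reported for that sample.

All numbers are stored exactly as printed (dyads to 2 decimals,
parameters to 3).  ``expected_assessment`` is the published assessment
table for the same inputs and serves as a regression reference.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .norms import SRMPopulationParameters
from .roundrobin import RoleSet, RoundRobinData

__all__ = [
    "case_study_dyads",
    "norm_parameters",
    "norm_dyad_summary",
    "expected_assessment",
    "make_fixtures",
]

_ROLES = ("M", "F", "C1", "C2")

# Directed RS-anxiety scores of the family of interest.
_CASE_DYADS = {
    ("M", "F"): 1.00,
    ("M", "C1"): 1.00,
    ("M", "C2"): 2.00,
    ("F", "M"): 1.17,
    ("F", "C1"): 1.50,
    ("F", "C2"): 3.83,
    ("C1", "M"): 1.09,
    ("C1", "F"): 1.33,
    ("C1", "C2"): 2.83,
    ("C2", "M"): 1.17,
    ("C2", "F"): 4.83,
    ("C2", "C1"): 3.33,
}

# Norm-sample CFA estimates: variance and mean per SRM component.
_FAMILY_VAR, _FAMILY_MEAN = 0.039, 1.838
_ACTOR = {  # role: (variance, mean)
    "M": (0.163, -0.087),
    "F": (0.217, 0.103),
    "C1": (0.215, -0.134),
    "C2": (0.232, 0.117),
}
_PARTNER = {
    "M": (0.044, -0.169),
    "F": (0.056, 0.038),
    "C1": (0.064, 0.022),
    "C2": (0.079, 0.109),
}
_REL = {
    ("M", "F"): (0.491, 0.040),
    ("M", "C1"): (0.223, -0.028),
    ("M", "C2"): (0.338, -0.012),
    ("F", "M"): (0.616, 0.116),
    ("F", "C1"): (0.170, -0.066),
    ("F", "C2"): (0.205, -0.050),
    ("C1", "M"): (0.107, -0.059),
    ("C1", "F"): (0.204, -0.003),
    ("C1", "C2"): (0.205, 0.062),
    ("C2", "M"): (0.204, -0.057),
    ("C2", "F"): (0.336, -0.037),
    ("C2", "C1"): (0.356, 0.094),
}
# Reciprocity correlations of the norm sample.
_GENERALIZED = {"M": 0.40, "F": 0.03, "C1": 0.51, "C2": 0.54}
_DYADIC = {
    ("M", "F"): 0.35,
    ("M", "C1"): 0.16,
    ("M", "C2"): -0.00,
    ("F", "C1"): 0.22,
    ("F", "C2"): 0.19,
    ("C1", "C2"): 0.05,
}
# All SRM variances were significant at the 0.05 level in the norm study.
_VARIANCE_SIGNIFICANT = True

# Mean and SD of each raw dyadic measurement in the norm sample
# (used only as a cross-check of the model-implied dyad law).
_NORM_DYAD_SUMMARY = {
    ("M", "F"): (1.83, 0.88),
    ("M", "C1"): (1.75, 0.71),
    ("M", "C2"): (1.85, 0.78),
    ("F", "M"): (1.89, 0.91),
    ("F", "C1"): (1.90, 0.70),
    ("F", "C2"): (2.00, 0.74),
    ("C1", "M"): (1.48, 0.62),
    ("C1", "F"): (1.74, 0.74),
    ("C1", "C2"): (1.88, 0.75),
    ("C2", "M"): (1.73, 0.73),
    ("C2", "F"): (1.96, 0.83),
    ("C2", "C1"): (2.07, 0.77),
}

# Published assessment of the case family: effect, ANOVA score, Z, p.
_EXPECTED = [
    ("family", 2.090, 0.639, 0.523),
    ("actor:M", -1.206, -2.358, 0.018),
    ("actor:F", 0.198, 0.191, 0.849),
    ("actor:C1", -0.438, -0.628, 0.530),
    ("actor:C2", 1.446, 2.607, 0.009),
    ("partner:M", -1.349, -3.385, 0.001),
    ("partner:F", 0.363, 0.896, 0.370),
    ("partner:C1", -0.292, -0.853, 0.393),
    ("partner:C2", 1.279, 3.151, 0.002),
    ("rel:M->F", -0.246, -0.767, 0.443),
    ("rel:M->C1", 0.409, 1.304, 0.192),
    ("rel:M->C2", -0.163, -0.436, 0.663),
    ("rel:F->M", 0.231, 0.305, 0.761),
    ("rel:F->C1", -0.497, -1.350, 0.177),
    ("rel:F->C2", 0.264, 0.989, 0.323),
    ("rel:C1->M", 0.786, 2.856, 0.004),
    ("rel:C1->F", -0.685, -2.203, 0.028),
    ("rel:C1->C2", -0.101, -0.481, 0.631),
    ("rel:C2->M", -1.018, -2.910, 0.004),
    ("rel:C2->F", 0.931, 2.803, 0.005),
    ("rel:C2->C1", 0.086, -0.02, 0.984),
]


def case_study_dyads() -> RoundRobinData:
    """The case family's 12 directed RS-anxiety measurements."""
    return RoundRobinData(RoleSet(_ROLES), dict(_CASE_DYADS))


def norm_parameters() -> SRMPopulationParameters:
    """CFA-estimated SRM parameters of the 208-family norm sample."""
    roles = RoleSet(_ROLES)
    sig = {"family": _VARIANCE_SIGNIFICANT}
    sig.update({f"actor:{r}": _VARIANCE_SIGNIFICANT for r in _ROLES})
    sig.update({f"partner:{r}": _VARIANCE_SIGNIFICANT for r in _ROLES})
    sig.update({f"rel:{a}->{p}": _VARIANCE_SIGNIFICANT for a, p in _REL})
    return SRMPopulationParameters(
        roles=roles,
        family_mean=_FAMILY_MEAN,
        family_var=_FAMILY_VAR,
        actor_mean={r: m for r, (v, m) in _ACTOR.items()},
        actor_var={r: v for r, (v, m) in _ACTOR.items()},
        partner_mean={r: m for r, (v, m) in _PARTNER.items()},
        partner_var={r: v for r, (v, m) in _PARTNER.items()},
        rel_mean={d: m for d, (v, m) in _REL.items()},
        rel_var={d: v for d, (v, m) in _REL.items()},
        generalized_reciprocity=dict(_GENERALIZED),
        dyadic_reciprocity=dict(_DYADIC),
        reciprocity_scale="correlation",
        variance_significant=sig,
    )


def norm_dyad_summary() -> pd.DataFrame:
    """Published mean and SD of each raw dyadic measurement in the norm sample."""
    return pd.DataFrame(
        {
            "actor": [a for a, _ in _NORM_DYAD_SUMMARY],
            "partner": [p for _, p in _NORM_DYAD_SUMMARY],
            "mean": [m for m, _ in _NORM_DYAD_SUMMARY.values()],
            "sd": [s for _, s in _NORM_DYAD_SUMMARY.values()],
        }
    )


def expected_assessment() -> pd.DataFrame:
    """The published 21-row assessment table for the case family."""
    return pd.DataFrame(_EXPECTED, columns=["effect", "anova_score", "z", "p"])


def make_fixtures(target_dir: str | Path) -> list[Path]:
    """Write the worked example to disk as plain-text fixture files.

    Produces four files: the dyads in long and matrix CSV form, the norm
    parameters as JSON, and the expected assessment table as CSV.  Output
    is deterministic (byte-identical across runs).
    """
    from .io import write_dyads_long, write_dyads_matrix, write_norms

    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    data = case_study_dyads()
    params = norm_parameters()

    paths = [
        target / "case_dyads_long.csv",
        target / "case_dyads_matrix.csv",
        target / "norm_parameters.json",
        target / "expected_assessment.csv",
    ]
    write_dyads_long(data, paths[0])
    write_dyads_matrix(data, paths[1])
    write_norms(params, paths[2])
    expected_assessment().to_csv(paths[3], index=False)
    return paths
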