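"""Monte-Carlo simulation of four-person families from the SRM.

Families are drawn generatively from the model X_ij = Fam + Act_i +
Par_j + Rel_ij with multivariate-normal effects: the family effect is a
scalar normal, each person's (actor, partner) pair is bivariate normal
with the generalized-reciprocity covariance, and each unordered dyad's
two directed relationship effects are bivariate normal with the
dyadic-reciprocity covariance.  Draws do not impose per-family zero-sum
constraints -- those identify the population means, not realizations.

The simulator samples effect-by-effect (2x2 matrix square roots), which
makes it an independent check on the analytically assembled dyad law and
on the CFA-to-ANOVA transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .norms import (
    SRMPopulationParameters,
    anova_weight_matrix,
    dyad_law,
    reciprocity_to_covariance,
    sampling_distribution,
)
from .roundrobin import RoleSet, RoundRobinData, ValidationError, effect_ids

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_families",
    "empirical_sampling_check",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters, family count and seed for one reproducible run.

    ``repair`` opts in to clipping negative eigenvalues of a (numerically)
    indefinite 2x2 effect block at zero; by default such blocks raise.
    """

    params: SRMPopulationParameters
    n_families: int
    seed: int
    repair: bool = False

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValidationError(f"n_families must be >= 1, got {self.n_families}")


@dataclass(frozen=True)
class SimulationResult:
    """Simulated dyad vectors plus per-effect empirical summaries.

    ``dyads`` is an (n_families, 12) array in canonical dyad order;
    ``summary`` holds the empirical mean and SD of each ANOVA score
    across families.
    """

    roles: RoleSet
    dyads: np.ndarray
    summary: pd.DataFrame

    @property
    def n_families(self) -> int:
        return self.dyads.shape[0]

    def family(self, i: int) -> RoundRobinData:
        return RoundRobinData.from_vector(self.dyads[i], self.roles)

    def families(self) -> list[RoundRobinData]:
        return [self.family(i) for i in range(self.n_families)]

    def anova_scores(self) -> np.ndarray:
        """(n_families, 21) matrix of ANOVA scores, canonical effect order."""
        W = anova_weight_matrix(self.roles)
        return self.dyads @ W.T

    def to_long_frame(self) -> pd.DataFrame:
        """Long table family_id, actor, partner, value."""
        dyads = self.roles.dyads
        n = self.n_families
        return pd.DataFrame(
            {
                "family_id": np.repeat(np.arange(n), 12),
                "actor": np.tile([a for a, _ in dyads], n),
                "partner": np.tile([p for _, p in dyads], n),
                "value": self.dyads.ravel(),
            }
        )


def _sqrt_2x2(block: np.ndarray, label: str, repair: bool) -> np.ndarray:
    """Symmetric square root of a 2x2 covariance block.

    Uses the eigendecomposition so that zero-variance (degenerate) blocks
    reduce to constants instead of failing a Cholesky factorization.
    Materially negative eigenvalues raise unless ``repair`` clips them.
    """
    vals, vecs = np.linalg.eigh(block)
    if vals.min() < -1e-10:
        if not repair:
            raise ValidationError(
                f"covariance block for {label} is not positive semidefinite "
                f"(smallest eigenvalue {vals.min():.3e}); pass repair=True to "
                "clip it at zero"
            )
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def simulate_families(config: SimulationConfig) -> SimulationResult:
    """Draw ``n_families`` independent families from the norm population.

    A single NumPy generator keyed by the seed drives all draws; the draw
    order is fixed (family effects, then persons in role order, then
    unordered dyads), so identical configs give bit-identical results.
    """
    p = reciprocity_to_covariance(config.params)
    roles = p.roles
    n = config.n_families
    rng = np.random.default_rng(config.seed)

    if p.family_var < 0:
        raise ValidationError(f"family variance is negative: {p.family_var}")
    fam = p.family_mean + np.sqrt(p.family_var) * rng.standard_normal(n)

    actor = {}
    partner = {}
    for r in roles.labels:
        block = np.array(
            [
                [p.actor_var[r], p.generalized_reciprocity[r]],
                [p.generalized_reciprocity[r], p.partner_var[r]],
            ]
        )
        L = _sqrt_2x2(block, f"person {r} (actor/partner)", config.repair)
        draws = rng.standard_normal((n, 2)) @ L.T
        actor[r] = p.actor_mean[r] + draws[:, 0]
        partner[r] = p.partner_mean[r] + draws[:, 1]

    rel = {}
    for a, b in roles.unordered_dyads:
        block = np.array(
            [
                [p.rel_var[(a, b)], p.dyadic_reciprocity[(a, b)]],
                [p.dyadic_reciprocity[(a, b)], p.rel_var[(b, a)]],
            ]
        )
        L = _sqrt_2x2(block, f"dyad {a}<->{b} (relationship)", config.repair)
        draws = rng.standard_normal((n, 2)) @ L.T
        rel[(a, b)] = p.rel_mean[(a, b)] + draws[:, 0]
        rel[(b, a)] = p.rel_mean[(b, a)] + draws[:, 1]

    dyads = np.empty((n, 12))
    for c, (a, b) in enumerate(roles.dyads):
        dyads[:, c] = fam + actor[a] + partner[b] + rel[(a, b)]

    W = anova_weight_matrix(roles)
    scores = dyads @ W.T
    summary = pd.DataFrame(
        {
            "effect": effect_ids(roles),
            "empirical_mean": scores.mean(axis=0),
            "empirical_sd": scores.std(axis=0, ddof=1) if n > 1 else np.zeros(21),
        }
    )
    return SimulationResult(roles=roles, dyads=dyads, summary=summary)


def empirical_sampling_check(config: SimulationConfig) -> pd.DataFrame:
    """Compare analytic and simulated sampling distributions per effect.

    Returns 21 rows with the analytic mean/sd from linear propagation,
    the empirical mean/sd over simulated families, Monte-Carlo standard
    errors, and pass flags at 3 MC standard errors (42 comparisons in
    total).  The SD standard error uses the normal-theory approximation
    sd / sqrt(2(n-1)).
    """
    result = simulate_families(config)
    dist = sampling_distribution(config.params)
    n = config.n_families
    ids = effect_ids(config.params.roles)

    emp_mean = result.summary["empirical_mean"].to_numpy()
    emp_sd = result.summary["empirical_sd"].to_numpy()
    ana_mean = np.array([dist.mean[e] for e in ids])
    ana_sd = np.array([dist.sd[e] for e in ids])

    se_mean = ana_sd / np.sqrt(n)
    se_sd = ana_sd / np.sqrt(2.0 * max(n - 1, 1))
    # zero-variance effects are exactly constant in both routes
    pass_mean = np.abs(emp_mean - ana_mean) <= np.maximum(3 * se_mean, 1e-12)
    pass_sd = np.abs(emp_sd - ana_sd) <= np.maximum(3 * se_sd, 1e-12)

    return pd.DataFrame(
        {
            "effect": ids,
            "analytic_mean": ana_mean,
            "empirical_mean": emp_mean,
            "mc_se_mean": se_mean,
            "pass_mean": pass_mean,
            "analytic_sd": ana_sd,
            "empirical_sd": emp_sd,
            "mc_se_sd": se_sd,
            "pass_sd": pass_sd,
        }
    )
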