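"""Normative SRM population parameters and the CFA-to-ANOVA transformation.

Family studies typically report the means and variances of the latent SRM
effects estimated by a confirmatory factor analysis (CFA) on a norm sample
of families, together with generalized reciprocities (actor-partner
correlations within a person) and dyadic reciprocities (correlations
between the two directed relationship effects of an unordered dyad).
Those CFA quantities are not the mean and standard deviation of the
per-family ANOVA scores, which is what norm-referenced Z scoring needs.

The link is exact linear propagation.  Under the SRM the 12-dyad vector X
is multivariate with mean mu and covariance Sigma assembled from the CFA
parameters (effects independent except through the two reciprocity
patterns).  Every ANOVA score is a fixed linear functional w'X, so its
sampling distribution over norm families has mean w'mu and standard
deviation sqrt(w' Sigma w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

import numpy as np

from .roundrobin import RoleSet, ValidationError, effect_ids

__all__ = [
    "SRMPopulationParameters",
    "DyadLawOf12",
    "SamplingDistribution",
    "Diagnostic",
    "reciprocity_to_covariance",
    "dyad_law",
    "anova_weight_matrix",
    "sampling_distribution",
    "validate_params",
]

#: Below this standard deviation an effect is reported non-assessable.
SD_FLOOR = 1e-8

#: Zero-sum warnings allow for 3-decimal rounding of published tables.
ZERO_SUM_TOL = 0.01


@dataclass(frozen=True)
class SRMPopulationParameters:
    """CFA-estimated SRM means, variances and reciprocities of a norm sample.

    Reciprocities may be given as correlations or covariances;
    ``reciprocity_scale`` says which.  Dyadic reciprocities are keyed by
    unordered pairs in canonical role order.  ``variance_significant`` is
    an optional per-effect flag carried through to the report: Z scores of
    effects whose norm variance was not significant are footnoted.
    """

    roles: RoleSet
    family_mean: float
    family_var: float
    actor_mean: Mapping[str, float]
    actor_var: Mapping[str, float]
    partner_mean: Mapping[str, float]
    partner_var: Mapping[str, float]
    rel_mean: Mapping[Tuple[str, str], float]
    rel_var: Mapping[Tuple[str, str], float]
    generalized_reciprocity: Mapping[str, float]
    dyadic_reciprocity: Mapping[Tuple[str, str], float]
    reciprocity_scale: str = "correlation"
    variance_significant: Mapping[str, bool] | None = None

    def __post_init__(self) -> None:
        if self.reciprocity_scale not in ("correlation", "covariance"):
            raise ValidationError(
                f"reciprocity_scale must be 'correlation' or 'covariance', "
                f"got {self.reciprocity_scale!r}"
            )
        for name, mapping, keys in (
            ("actor_mean", self.actor_mean, self.roles.labels),
            ("actor_var", self.actor_var, self.roles.labels),
            ("partner_mean", self.partner_mean, self.roles.labels),
            ("partner_var", self.partner_var, self.roles.labels),
            ("generalized_reciprocity", self.generalized_reciprocity, self.roles.labels),
            ("rel_mean", self.rel_mean, self.roles.dyads),
            ("rel_var", self.rel_var, self.roles.dyads),
            ("dyadic_reciprocity", self.dyadic_reciprocity, self.roles.unordered_dyads),
        ):
            missing = [k for k in keys if k not in mapping]
            if missing:
                raise ValidationError(f"{name} is missing entries for {missing}")
        errors = [d for d in validate_params(self) if d.severity == "error"]
        if errors:
            raise ValidationError("; ".join(d.message for d in errors))


@dataclass(frozen=True)
class Diagnostic:
    """A validation finding: severity is ``"warning"`` or ``"error"``."""

    severity: str
    message: str


def validate_params(params: SRMPopulationParameters) -> list[Diagnostic]:
    """Check a parameter set for range and consistency problems.

    Negative variances and out-of-range correlations (or covariances
    violating the Cauchy-Schwarz bound) are errors.  Deviations of the
    mean structure from the identifying zero-sum constraints beyond 0.01
    are warnings only, since published tables are rounded.
    """
    out: list[Diagnostic] = []
    roles = params.roles

    def _check_var(name: str, v: float) -> None:
        if v < 0:
            out.append(Diagnostic("error", f"{name} variance is negative: {v}"))

    _check_var("family", params.family_var)
    for r in roles.labels:
        _check_var(f"actor {r}", params.actor_var[r])
        _check_var(f"partner {r}", params.partner_var[r])
    for d in roles.dyads:
        _check_var(f"relationship {d[0]}->{d[1]}", params.rel_var[d])

    if params.reciprocity_scale == "correlation":
        for r in roles.labels:
            rho = params.generalized_reciprocity[r]
            if abs(rho) > 1:
                out.append(
                    Diagnostic("error", f"generalized reciprocity of {r} out of [-1, 1]: {rho}")
                )
        for a, b in roles.unordered_dyads:
            rho = params.dyadic_reciprocity[(a, b)]
            if abs(rho) > 1:
                out.append(
                    Diagnostic("error", f"dyadic reciprocity of {a}<->{b} out of [-1, 1]: {rho}")
                )
    else:
        for r in roles.labels:
            c = params.generalized_reciprocity[r]
            bound = math.sqrt(max(params.actor_var[r], 0.0) * max(params.partner_var[r], 0.0))
            if abs(c) > bound + 1e-12:
                out.append(
                    Diagnostic(
                        "error",
                        f"generalized reciprocity covariance of {r} ({c}) exceeds "
                        f"Cauchy-Schwarz bound {bound:.6g}",
                    )
                )
        for a, b in roles.unordered_dyads:
            c = params.dyadic_reciprocity[(a, b)]
            bound = math.sqrt(
                max(params.rel_var[(a, b)], 0.0) * max(params.rel_var[(b, a)], 0.0)
            )
            if abs(c) > bound + 1e-12:
                out.append(
                    Diagnostic(
                        "error",
                        f"dyadic reciprocity covariance of {a}<->{b} ({c}) exceeds "
                        f"Cauchy-Schwarz bound {bound:.6g}",
                    )
                )

    # Identifying constraints hold on the population means; printed
    # estimates should satisfy them up to rounding.
    s = sum(params.actor_mean[r] for r in roles.labels)
    if abs(s) > ZERO_SUM_TOL:
        out.append(Diagnostic("warning", f"actor means sum to {s:.4g}, expected 0"))
    s = sum(params.partner_mean[r] for r in roles.labels)
    if abs(s) > ZERO_SUM_TOL:
        out.append(Diagnostic("warning", f"partner means sum to {s:.4g}, expected 0"))
    for r in roles.labels:
        s = sum(params.rel_mean[(r, p)] for p in roles.labels if p != r)
        if abs(s) > ZERO_SUM_TOL:
            out.append(
                Diagnostic("warning", f"relationship means of actor {r} sum to {s:.4g}, expected 0")
            )
        s = sum(params.rel_mean[(a, r)] for a in roles.labels if a != r)
        if abs(s) > ZERO_SUM_TOL:
            out.append(
                Diagnostic("warning", f"relationship means of partner {r} sum to {s:.4g}, expected 0")
            )
    return out


def reciprocity_to_covariance(
    params: SRMPopulationParameters,
) -> SRMPopulationParameters:
    """Return an equivalent parameter set with reciprocities as covariances.

    A generalized reciprocity correlation r becomes
    ``r * sqrt(actor_var * partner_var)`` for that person; a dyadic
    reciprocity correlation becomes ``r * sqrt(rel_var_ij * rel_var_ji)``.
    Covariance-scale input passes through unchanged (the constructor has
    already enforced the Cauchy-Schwarz bounds).
    """
    if params.reciprocity_scale == "covariance":
        return params
    roles = params.roles
    gen = {
        r: params.generalized_reciprocity[r]
        * math.sqrt(params.actor_var[r] * params.partner_var[r])
        for r in roles.labels
    }
    dyad = {
        (a, b): params.dyadic_reciprocity[(a, b)]
        * math.sqrt(params.rel_var[(a, b)] * params.rel_var[(b, a)])
        for a, b in roles.unordered_dyads
    }
    return replace(
        params,
        generalized_reciprocity=gen,
        dyadic_reciprocity=dyad,
        reciprocity_scale="covariance",
    )


@dataclass(frozen=True)
class DyadLawOf12:
    """Model-implied distribution of the 12-dyad vector in the norm population.

    ``mean`` and ``covariance`` follow the canonical actor-major dyad
    order of ``roles``.  ``min_eigenvalue`` reports how close the
    assembled covariance is to the positive-semidefinite boundary;
    inconsistent published estimates can push it slightly negative.
    """

    roles: RoleSet
    mean: np.ndarray
    covariance: np.ndarray
    min_eigenvalue: float = field(init=False)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (12,) or cov.shape != (12, 12):
            raise ValidationError("dyad law requires a 12-vector mean and 12x12 covariance")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("dyad covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(
            self, "min_eigenvalue", float(np.linalg.eigvalsh(cov).min())
        )


def dyad_law(params: SRMPopulationParameters) -> DyadLawOf12:
    """Assemble the mean and covariance of the 12 dyadic measurements.

    Mean: ``family + actor_i + partner_j + rel_ij`` per dyad.  Covariance:
    the family variance is shared by every pair of dyads; actor (partner)
    variances link dyads with the same actor (partner); generalized
    reciprocity links a person's outgoing and incoming dyads; relationship
    variances sit on the diagonal and dyadic reciprocity links the two
    directions of each unordered dyad.  All other cross terms are zero.
    """
    p = reciprocity_to_covariance(params)
    roles = p.roles
    dyads = roles.dyads
    mean = np.array(
        [
            p.family_mean + p.actor_mean[a] + p.partner_mean[b] + p.rel_mean[(a, b)]
            for a, b in dyads
        ]
    )
    cov = np.full((12, 12), float(p.family_var))
    for r, (i, j) in enumerate(dyads):
        for c, (k, l) in enumerate(dyads):
            v = 0.0
            if i == k:
                v += p.actor_var[i]
            if j == l:
                v += p.partner_var[j]
            if i == l:
                v += p.generalized_reciprocity[i]
            if j == k:
                v += p.generalized_reciprocity[j]
            if (i, j) == (k, l):
                v += p.rel_var[(i, j)]
            elif (i, j) == (l, k):
                v += p.dyadic_reciprocity[roles.sort_pair(i, j)]
            cov[r, c] += v
    return DyadLawOf12(roles=roles, mean=mean, covariance=cov)


def anova_weight_matrix(roles: RoleSet) -> np.ndarray:
    """The 21x12 matrix mapping a dyad vector to the 21 ANOVA scores.

    Rows follow the canonical effect order (family, actors, partners,
    relationships); columns the actor-major dyad order.  The family row is
    1/12 everywhere; an actor row puts 1/4 on that person's outgoing
    dyads, 0 on the incoming ones and -1/8 elsewhere (the algebraic
    restatement of the weighted row/column/grand-mean estimator); partner
    rows mirror that; each relationship row is the dyad indicator minus
    the family, actor and partner rows.
    """
    dyads = roles.dyads
    n_eff = len(effect_ids(roles))
    W = np.zeros((n_eff, 12))
    W[0, :] = 1.0 / 12.0

    actor_rows = {r: 1 + i for i, r in enumerate(roles.labels)}
    partner_rows = {r: 5 + i for i, r in enumerate(roles.labels)}
    for r in roles.labels:
        for c, (a, p) in enumerate(dyads):
            if a == r:
                W[actor_rows[r], c] = 0.25
                W[partner_rows[r], c] = 0.0
            elif p == r:
                W[actor_rows[r], c] = 0.0
                W[partner_rows[r], c] = 0.25
            else:
                W[actor_rows[r], c] = -0.125
                W[partner_rows[r], c] = -0.125

    for k, (a, p) in enumerate(dyads):
        row = 9 + k
        W[row, roles.dyad_index(a, p)] = 1.0
        W[row, :] -= W[0, :] + W[actor_rows[a], :] + W[partner_rows[p], :]
    return W


@dataclass(frozen=True)
class SamplingDistribution:
    """Norm mean and standard deviation of each of the 21 ANOVA scores.

    These are the reference quantities for Z scoring.  Effects whose sd
    falls below ``SD_FLOOR`` cannot be standardized and are listed in
    ``non_assessable``.
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]

    @property
    def non_assessable(self) -> tuple[str, ...]:
        return tuple(e for e, s in self.sd.items() if s < SD_FLOOR)


def sampling_distribution(params: SRMPopulationParameters) -> SamplingDistribution:
    """Propagate CFA parameters to the ANOVA scores' norm distribution.

    For effect k with weight row w_k: mean = w_k . mu and
    sd = sqrt(w_k Sigma w_k') from the dyad law.  A materially negative
    quadratic form indicates a non-positive-semidefinite assembled
    covariance (inconsistent published estimates) and raises an error
    reporting the smallest eigenvalue.
    """
    law = dyad_law(params)
    W = anova_weight_matrix(params.roles)
    means = W @ law.mean
    variances = np.einsum("ij,jk,ik->i", W, law.covariance, W)
    if variances.min() < -1e-10:
        raise ValidationError(
            "assembled dyad covariance is not positive semidefinite "
            f"(smallest eigenvalue {law.min_eigenvalue:.3e}); check the norm "
            "parameter estimates for consistency"
        )
    sds = np.sqrt(np.clip(variances, 0.0, None))
    ids = effect_ids(params.roles)
    return SamplingDistribution(
        mean=dict(zip(ids, means.tolist())),
        sd=dict(zip(ids, sds.tolist())),
    )
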