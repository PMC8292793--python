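"""Round-robin data model and per-family SRM ANOVA scores.

A four-person round robin yields 12 directed dyadic measurements (each
member rates every other member; no self-ratings).  The Social Relations
Model (SRM) writes each measurement as

    X_ij = Fam + Act_i + Par_j + Rel_ij

with a family effect shared by all dyads, an actor effect for the rater,
a partner effect for the target, and a directed relationship residual.
Because the diagonal of the round-robin table is empty, the per-family
estimates ("ANOVA scores") of the actor and partner effects are weighted
combinations of the row mean, the column mean, and the grand mean rather
than the raw row/column means; with n = 4 the weights are 9/8, 3/8 and
-3/2.  Relationship scores are the residuals after removing the family,
actor, and partner components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "DEFAULT_ROLES",
    "ValidationError",
    "RoleSet",
    "RoundRobinData",
    "AnovaScores",
    "effect_ids",
    "grand_mean",
    "row_col_means",
    "actor_score",
    "partner_score",
    "relationship_score",
    "decompose",
]

#: Conventional role labels: mother, father, oldest child, youngest child.
DEFAULT_ROLES: Tuple[str, ...] = ("M", "F", "C1", "C2")

FAMILY_SIZE = 4

# Eq. weights for the n = 4 missing-diagonal round robin:
#   (n-1)^2 / [n(n-2)],  (n-1) / [n(n-2)],  (n-1)/(n-2)
_W_OWN = 9.0 / 8.0
_W_CROSS = 3.0 / 8.0
_W_GRAND = 3.0 / 2.0


class ValidationError(ValueError):
    """Raised when round-robin input data violate the design contract."""


@dataclass(frozen=True)
class RoleSet:
    """An ordered set of exactly four distinct role labels.

    The label order is canonical: it fixes the order of every vector and
    matrix produced downstream (dyads are enumerated actor-major).
    """

    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) != FAMILY_SIZE:
            raise ValidationError(
                f"exactly {FAMILY_SIZE} roles are required, got {len(labels)}: {labels!r}"
            )
        if len(set(labels)) != FAMILY_SIZE:
            raise ValidationError(f"role labels must be distinct, got {labels!r}")
        if any(not lab for lab in labels):
            raise ValidationError("role labels must be non-empty strings")

    @classmethod
    def default(cls) -> "RoleSet":
        return cls(DEFAULT_ROLES)

    @property
    def dyads(self) -> Tuple[Tuple[str, str], ...]:
        """The 12 directed dyads in canonical actor-major order."""
        return tuple(
            (a, p) for a in self.labels for p in self.labels if a != p
        )

    @property
    def unordered_dyads(self) -> Tuple[Tuple[str, str], ...]:
        """The 6 unordered dyads, each as (earlier role, later role)."""
        labs = self.labels
        return tuple(
            (labs[i], labs[j])
            for i in range(FAMILY_SIZE)
            for j in range(i + 1, FAMILY_SIZE)
        )

    def index(self, role: str) -> int:
        try:
            return self.labels.index(role)
        except ValueError:
            raise ValidationError(
                f"unknown role {role!r}; expected one of {self.labels!r}"
            ) from None

    def dyad_index(self, actor: str, partner: str) -> int:
        if actor == partner:
            raise ValidationError(f"self-pair ({actor!r}, {partner!r}) is not a dyad")
        i, j = self.index(actor), self.index(partner)
        # actor-major enumeration skips the diagonal cell of each row
        return i * (FAMILY_SIZE - 1) + j - (1 if j > i else 0)

    def sort_pair(self, a: str, b: str) -> Tuple[str, str]:
        """Order an unordered pair by canonical role order."""
        return (a, b) if self.index(a) < self.index(b) else (b, a)


def effect_ids(roles: RoleSet) -> Tuple[str, ...]:
    """Canonical identifiers of the 21 SRM effects, in fixed order.

    Order: ``family``, then ``actor:<role>`` (role order), then
    ``partner:<role>``, then ``rel:<actor>-><partner>`` (actor-major).
    """
    out = ["family"]
    out += [f"actor:{r}" for r in roles.labels]
    out += [f"partner:{r}" for r in roles.labels]
    out += [f"rel:{a}->{p}" for a, p in roles.dyads]
    return tuple(out)


@dataclass(frozen=True)
class RoundRobinData:
    """One family's complete round robin: 12 directed measurements.

    Parameters
    ----------
    roles
        The four role labels in canonical order.
    values
        Mapping from ordered ``(actor, partner)`` pairs to the measurement
        on the instrument's own scale (mean or sum score).  All 12
        non-diagonal pairs must be present and finite.
    """

    roles: RoleSet
    values: Mapping[Tuple[str, str], float]

    def __post_init__(self) -> None:
        vals = {}
        expected = set(self.roles.dyads)
        for key, v in dict(self.values).items():
            a, p = key
            if a == p:
                raise ValidationError(f"self-rating ({a!r}, {a!r}) is not allowed")
            if (a, p) not in expected:
                raise ValidationError(
                    f"pair ({a!r}, {p!r}) does not match roles {self.roles.labels!r}"
                )
            v = float(v)
            if not math.isfinite(v):
                raise ValidationError(f"value for ({a!r}, {p!r}) is not finite: {v!r}")
            vals[(a, p)] = v
        missing = sorted(expected - set(vals), key=lambda d: self.roles.dyad_index(*d))
        if missing:
            raise ValidationError(f"missing dyad values for pairs: {missing}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_vector(
        cls, vector: Iterable[float], roles: RoleSet | None = None
    ) -> "RoundRobinData":
        """Build from a 12-vector in canonical actor-major dyad order."""
        roles = roles or RoleSet.default()
        vec = list(vector)
        if len(vec) != 12:
            raise ValidationError(f"expected 12 dyad values, got {len(vec)}")
        return cls(roles, dict(zip(roles.dyads, vec)))

    def vector(self) -> np.ndarray:
        """The 12 measurements as an array in canonical dyad order."""
        return np.array([self.values[d] for d in self.roles.dyads], dtype=float)

    def matrix(self) -> np.ndarray:
        """The 4x4 actor-by-partner table with NaN on the diagonal."""
        m = np.full((FAMILY_SIZE, FAMILY_SIZE), np.nan)
        for (a, p), v in self.values.items():
            m[self.roles.index(a), self.roles.index(p)] = v
        return m


@dataclass(frozen=True)
class AnovaScores:
    """The 21 estimated SRM effects for a single family.

    ``family + actor[i] + partner[j] + relationship[(i, j)]`` reconstructs
    the raw measurement ``X_ij`` exactly; actor and partner scores each sum
    to zero, as do the relationship scores of any given actor or partner.
    """

    roles: RoleSet
    family: float
    actor: Mapping[str, float]
    partner: Mapping[str, float]
    relationship: Mapping[Tuple[str, str], float]

    def as_dict(self) -> dict[str, float]:
        """All 21 scores keyed by canonical effect identifier."""
        out = {"family": self.family}
        for r in self.roles.labels:
            out[f"actor:{r}"] = self.actor[r]
        for r in self.roles.labels:
            out[f"partner:{r}"] = self.partner[r]
        for a, p in self.roles.dyads:
            out[f"rel:{a}->{p}"] = self.relationship[(a, p)]
        return out

    def as_vector(self) -> np.ndarray:
        return np.array(list(self.as_dict().values()), dtype=float)


def grand_mean(data: RoundRobinData) -> float:
    """Family mean: the average of the 12 dyadic measurements."""
    return float(data.vector().mean())


def row_col_means(data: RoundRobinData) -> tuple[dict[str, float], dict[str, float]]:
    """Per-role row means (outgoing ratings) and column means (incoming).

    The row mean is a person's average rating of the other three members;
    the column mean is the average rating of that person by the others.
    """
    rows: dict[str, float] = {}
    cols: dict[str, float] = {}
    for r in data.roles.labels:
        rows[r] = float(
            np.mean([data.values[(r, p)] for p in data.roles.labels if p != r])
        )
        cols[r] = float(
            np.mean([data.values[(a, r)] for a in data.roles.labels if a != r])
        )
    return rows, cols


def actor_score(data: RoundRobinData, role: str) -> float:
    """ANOVA score of a role's actor effect.

    The empty diagonal biases the raw row mean, so the estimator reweights:
    ``(9/8)*row_mean + (3/8)*column_mean - (3/2)*grand_mean`` for n = 4.
    """
    data.roles.index(role)
    rows, cols = row_col_means(data)
    return _W_OWN * rows[role] + _W_CROSS * cols[role] - _W_GRAND * grand_mean(data)


def partner_score(data: RoundRobinData, role: str) -> float:
    """ANOVA score of a role's partner effect (row/column weights swapped)."""
    data.roles.index(role)
    rows, cols = row_col_means(data)
    return _W_OWN * cols[role] + _W_CROSS * rows[role] - _W_GRAND * grand_mean(data)


def relationship_score(data: RoundRobinData, actor: str, partner: str) -> float:
    """Directed relationship score: the dyadic residual.

    ``X[actor, partner] - actor_score - partner_score - grand_mean``.  With
    a single indicator per dyad this residual also absorbs measurement
    error, so it is interpreted with care.
    """
    if actor == partner:
        raise ValidationError(f"self-pair ({actor!r}, {partner!r}) has no relationship score")
    return (
        data.values[(actor, partner)]
        - actor_score(data, actor)
        - partner_score(data, partner)
        - grand_mean(data)
    )


def decompose(data: RoundRobinData) -> AnovaScores:
    """Compute all 21 SRM ANOVA scores for one family.

    Returns scores satisfying the zero-sum constraints and reconstructing
    each raw measurement as family + actor + partner + relationship.
    """
    fam = grand_mean(data)
    rows, cols = row_col_means(data)
    actor = {
        r: _W_OWN * rows[r] + _W_CROSS * cols[r] - _W_GRAND * fam
        for r in data.roles.labels
    }
    partner = {
        r: _W_OWN * cols[r] + _W_CROSS * rows[r] - _W_GRAND * fam
        for r in data.roles.labels
    }
    relationship = {
        (a, p): data.values[(a, p)] - actor[a] - partner[p] - fam
        for a, p in data.roles.dyads
    }
    return AnovaScores(
        roles=data.roles,
        family=fam,
        actor=actor,
        partner=partner,
        relationship=relationship,
    )
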