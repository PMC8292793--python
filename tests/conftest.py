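import numpy as np
import pytest

from srmfam import fixtures
from srmfam.norms import SRMPopulationParameters
from srmfam.roundrobin import RoleSet, RoundRobinData


@pytest.fixture(scope="session")
def case_data() -> RoundRobinData:
    """The worked-example family's 12 directed RS-anxiety scores."""
    return fixtures.case_study_dyads()


@pytest.fixture(scope="session")
def norm_params() -> SRMPopulationParameters:
    """CFA norm parameters of the 208-family reference sample."""
    return fixtures.norm_parameters()


@pytest.fixture(scope="session")
def expected_report():
    """Published 21-row assessment table for the worked example."""
    return fixtures.expected_assessment().set_index("effect")


@pytest.fixture
def roles() -> RoleSet:
    return RoleSet.default()


def _zero_sum_means(rng: np.random.Generator, roles: RoleSet):
    """Random SRM means satisfying the identifying constraints exactly.

    Actor and partner means are centered; relationship means are
    double-centered over the off-diagonal cells of the 4x4 table so that
    each actor's three and each partner's three relationship means sum
    to zero.
    """
    a = rng.normal(size=4)
    a -= a.mean()
    p = rng.normal(size=4)
    p -= p.mean()
    # double-center a random off-diagonal table by alternating projections
    m = rng.normal(size=(4, 4))
    np.fill_diagonal(m, 0.0)
    for _ in range(200):
        m -= m.sum(axis=1, keepdims=True) / 3.0
        np.fill_diagonal(m, 0.0)
        m -= m.sum(axis=0, keepdims=True) / 3.0
        np.fill_diagonal(m, 0.0)
    labs = roles.labels
    return (
        dict(zip(labs, a)),
        dict(zip(labs, p)),
        {(labs[i], labs[j]): m[i, j] for i in range(4) for j in range(4) if i != j},
    )


@pytest.fixture
def zero_var_params(roles) -> SRMPopulationParameters:
    """Degenerate norm population: every variance and reciprocity zero."""
    return SRMPopulationParameters(
        roles=roles,
        family_mean=2.0,
        family_var=0.0,
        actor_mean=dict.fromkeys(roles.labels, 0.0),
        actor_var=dict.fromkeys(roles.labels, 0.0),
        partner_mean=dict.fromkeys(roles.labels, 0.0),
        partner_var=dict.fromkeys(roles.labels, 0.0),
        rel_mean=dict.fromkeys(roles.dyads, 0.0),
        rel_var=dict.fromkeys(roles.dyads, 0.0),
        generalized_reciprocity=dict.fromkeys(roles.labels, 0.0),
        dyadic_reciprocity=dict.fromkeys(roles.unordered_dyads, 0.0),
        reciprocity_scale="correlation",
    )


@pytest.fixture
def exact_params(roles) -> SRMPopulationParameters:
    """A synthetic parameter set whose means satisfy the zero-sum
    constraints to machine precision (useful for unbiasedness checks)."""
    rng = np.random.default_rng(2024)
    am, pm, rm = _zero_sum_means(rng, roles)
    labs = roles.labels
    return SRMPopulationParameters(
        roles=roles,
        family_mean=2.5,
        family_var=0.05,
        actor_mean=am,
        actor_var={r: v for r, v in zip(labs, rng.uniform(0.05, 0.3, 4))},
        partner_mean=pm,
        partner_var={r: v for r, v in zip(labs, rng.uniform(0.02, 0.2, 4))},
        rel_mean=rm,
        rel_var={d: v for d, v in zip(roles.dyads, rng.uniform(0.1, 0.5, 12))},
        generalized_reciprocity={r: v for r, v in zip(labs, rng.uniform(-0.6, 0.6, 4))},
        dyadic_reciprocity={
            d: v for d, v in zip(roles.unordered_dyads, rng.uniform(-0.5, 0.5, 6))
        },
        reciprocity_scale="correlation",
    )
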