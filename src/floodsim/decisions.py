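"""Expected-cost reasoning and the citizen decision profiles.

Given subjective event probabilities ``(P(e1), P(e2), P(e3))`` a citizen
scores each of the three protective-investment levels by its probabilistic
total cost — investment outlay plus expected residual damage, minus any
incentive, plus any expected fine — and picks the cheapest.  Two cost systems
exist: the *independent* one, where each citizen bears only the damage its own
choice implies, and the *interdependent* one, where damage is shared across a
neighborhood so the own-damage terms shrink with neighborhood size while new
terms price the damage expected to arrive from distrusted neighbors.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

from .config import EconomicParams
from .sources import NONE, MEDIUM, MAXIMAL, argmax_severity


def fines_active(policy: str) -> bool:
    return policy in ("punitive", "punitive_and_encouraging")


def incentives_active(policy: str) -> bool:
    return policy in ("encouraging", "punitive_and_encouraging")


def investment_cost(level: int, econ: EconomicParams) -> float:
    if level == MAXIMAL:
        return econ.max_investment
    if level == MEDIUM:
        return econ.med_investment
    return 0.0


class NeighborhoodContext(NamedTuple):
    """What an interdependent citizen knows about its neighborhood:
    how many neighbors it has and how much it trusts the social source."""

    n_neighbors: int
    social_trust: float


def neighbor_damage_expectation(
    n: int, social_trust: float, econ: EconomicParams
) -> tuple[float, float]:
    """Expected critical/medium damage received from neighbors (CDFN, MDFN).

    Scaled by distrust in the social source: the more a citizen believes its
    neighbors decide correctly, the less damage it expects from them.  Both
    vanish with no neighbors or full trust.
    """
    if n < 0:
        raise ValueError("neighbor count must be non-negative")
    if not 0.0 <= social_trust <= 1.0:
        raise ValueError(f"social_trust must be in [0, 1], got {social_trust}")
    cdfn = econ.max_damage / (n + 1) * n * (1.0 - social_trust)
    return cdfn, cdfn / 2.0


def _fine_terms(
    econ: EconomicParams, policy: str, indication: Optional[int]
) -> tuple[float, float]:
    """Expected fine added to (medium, none) candidate costs.

    With ``indication=None`` (a citizen that never consults the authority)
    the unconditional expected-fine terms apply.  A citizen that sees the
    indication prices a fine only where it would actually risk one: the half
    fine on a medium investment under a critical indication, the full fine on
    no investment under any investing indication.
    """
    if not fines_active(policy):
        return 0.0, 0.0
    expected = econ.fine_amount * econ.fine_probability
    if indication is None:
        return expected / 2.0, expected
    med = expected / 2.0 if indication == MAXIMAL else 0.0
    none = expected if indication >= MEDIUM else 0.0
    return med, none


def expected_costs_independent(
    probs,
    econ: EconomicParams,
    policy: str,
    indication: Optional[int] = None,
) -> tuple[float, float, float]:
    """Probabilistic total cost of each level, own damage fully borne.

    Returns ``(cost_none, cost_medium, cost_maximal)`` indexed by level.
    """
    _, p2, p3 = probs
    incentive = (
        econ.incentive_rate * econ.max_investment if incentives_active(policy) else 0.0
    )
    fine_med, fine_none = _fine_terms(econ, policy, indication)
    cost_max = econ.max_investment + econ.max_damage / 4.0 * p3 - incentive
    cost_med = (
        econ.max_investment / 2.0
        + econ.max_damage / 2.0 * p3
        - incentive / 2.0
        + fine_med
    )
    cost_none = econ.max_damage * p3 + econ.med_damage * p2 + fine_none
    return cost_none, cost_med, cost_max


def expected_costs_interdependent(
    probs,
    econ: EconomicParams,
    policy: str,
    nbhd: NeighborhoodContext,
    indication: Optional[int] = None,
) -> tuple[float, float, float]:
    """Costs under neighborhood damage sharing.

    Own critical damage is split over the ``n + 1`` household-neighborhood
    members, and the expected inflow of neighbor-caused damage (CDFN/MDFN,
    discounted by social trust) is priced in, reduced by the citizen's own
    protection level.  With zero neighbors this reduces exactly to the
    independent costs.
    """
    _, p2, p3 = probs
    n = nbhd.n_neighbors
    incentive = (
        econ.incentive_rate * econ.max_investment if incentives_active(policy) else 0.0
    )
    fine_med, fine_none = _fine_terms(econ, policy, indication)
    cdfn, mdfn = neighbor_damage_expectation(n, nbhd.social_trust, econ)
    share = n + 1
    cost_max = (
        econ.max_investment
        + econ.max_damage / (4.0 * share) * p3
        - incentive
        + cdfn / 4.0 * p3
    )
    cost_med = (
        econ.max_investment / 2.0
        + econ.max_damage / (2.0 * share) * p3
        - incentive / 2.0
        + fine_med
        + cdfn / 2.0 * p3
    )
    cost_none = (
        econ.max_damage / share * p3
        + econ.med_damage * p2
        + fine_none
        + cdfn * p3
        + mdfn * p2
    )
    return cost_none, cost_med, cost_max


def argmin_cost_level(costs) -> int:
    """Cheapest level; exact ties resolve toward the higher (safer) investment."""
    best = MAXIMAL
    for level in (MEDIUM, NONE):
        if costs[level] < costs[best]:
            best = level
    return best


def decide(
    profile: str,
    probs,
    econ: EconomicParams,
    policy: str,
    scenario: str = "independent",
    nbhd: Optional[NeighborhoodContext] = None,
    indication: Optional[int] = None,
    rng=None,
) -> int:
    """One citizen's investment choice, by profile strategy.

    ``probs`` must be the a-priori event distribution for ``ap``/``apc`` and
    the aggregated-source probabilities for ``es``/``esc`` (whose information
    policy is to consult sources).  ``random`` draws uniformly; ``free_rider``
    never invests.
    """
    if profile == "random":
        return int(rng.integers(3))
    if profile == "free_rider":
        return NONE
    if probs is None:
        raise ValueError(f"profile {profile!r} requires event probabilities")
    if profile == "ap":
        return argmax_severity([p * 3 for p in probs]) - 1
    if profile == "es":
        return argmax_severity([p * 3 for p in probs]) - 1
    if profile == "apc":
        costs = expected_costs_independent(probs, econ, policy, indication=None)
        return argmin_cost_level(costs)
    if profile == "esc":
        if scenario == "interdependent":
            if nbhd is None:
                raise ValueError("interdependent esc decision needs a NeighborhoodContext")
            costs = expected_costs_interdependent(
                probs, econ, policy, nbhd, indication=indication
            )
        else:
            costs = expected_costs_independent(probs, econ, policy, indication=indication)
        return argmin_cost_level(costs)
    raise ValueError(f"unknown profile {profile!r}")
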