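"""The authority's monetary instruments and capital accounting.

The authority forecasts (see :mod:`floodsim.sources`), pays incentives for
investments when its policy is encouraging, fines detected non-compliers when
punitive, and bears a configurable share of the citizens' incurred damage
(relief and reconstruction).  Its capital obeys the accounting identity
``capital = capital0 + fines_collected - incentives_paid - damage_borne`` at
all times.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import EconomicParams
from .decisions import fines_active, incentives_active, investment_cost
from .sources import MEDIUM, MAXIMAL, NONE


@dataclass
class AuthorityState:
    capital: float
    capital0: float
    fines_collected: float = 0.0
    incentives_paid: float = 0.0
    damage_borne: float = 0.0

    def check_identity(self, tol: float = 1e-6) -> None:
        expected = (
            self.capital0 + self.fines_collected - self.incentives_paid - self.damage_borne
        )
        assert abs(self.capital - expected) <= tol, (
            f"authority accounting identity violated: {self.capital} != {expected}"
        )


def incentive_for(decision_level: int, policy: str, econ: EconomicParams) -> float:
    """Incentive paid for an investment: ``incentive_rate`` times its cost,
    whenever incentives are active and the citizen invested anything."""
    if not incentives_active(policy):
        return 0.0
    return econ.incentive_rate * investment_cost(decision_level, econ)


def assess_fine(
    indication_level: int,
    decision_level: int,
    policy: str,
    econ: EconomicParams,
    rng,
) -> float:
    """Fine charged to one citizen for one event.

    A citizen is guilty when the authority indicated a higher investment than
    it made.  Detection is an independent Bernoulli draw per guilty citizen
    (the authority only discovers a fraction of offenders).  A detected
    citizen that invested nothing pays the full fine; one that made a medium
    investment under a critical indication pays half.
    """
    if not fines_active(policy):
        return 0.0
    if indication_level <= decision_level or indication_level == NONE:
        return 0.0
    if rng.random() >= econ.fine_probability:
        return 0.0
    if decision_level == NONE:
        return econ.fine_amount
    return econ.fine_amount / 2.0  # medium investment under a maximal indication


def settle_authority(
    state: AuthorityState,
    incentives: float,
    fines: float,
    citizen_damage_total: float,
    coeff: float,
) -> AuthorityState:
    """Post one event's flows to the authority's books."""
    if min(incentives, fines, citizen_damage_total) < 0:
        raise ValueError("settlement amounts must be non-negative")
    state.fines_collected += fines
    state.incentives_paid += incentives
    state.damage_borne += coeff * citizen_damage_total
    state.capital += fines - incentives - coeff * citizen_damage_total
    state.check_identity()
    return state
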