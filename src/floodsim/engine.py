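"""World geometry, the per-event loop, damage realization and replication.

A world is a 32×32 toroidal grid split into four equal quadrants that are
meteorologically independent: each event draws one true severity per quadrant.
Citizens are static, randomly placed within quadrants, and decide one at a
time in a fresh uniformly-random order; a citizen that has decided becomes
visible to later deciders through the social source, so the social signal
grows progressively informative within an event.

Damage realization is scenario-dependent.  Under the *independent* scenario a
citizen bears exactly the damage its own choice implies; under the
*interdependent* scenario the neighborhood pools damage — each member bears
the mean of the damages implied by every member's choice — which turns
individual protection into a shared good and makes free riding possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import beliefs
from .authority import AuthorityState, assess_fine, incentive_for, settle_authority
from .beliefs import FLAT, TrustLedger, aggregate, experience_weight, smooth_pdf
from .config import Config, profile_counts, validate_config
from .decisions import (
    NeighborhoodContext,
    argmin_cost_level,
    decide,
    expected_costs_independent,
    investment_cost,
)
from .sources import (
    MAXIMAL,
    MEDIUM,
    NONE,
    Forecast,
    argmax_severity,
    build_perception_model,
    forecast_from_pdf,
    perceive,
    social_pdf,
)

PROFILE_CODES = {"random": 0, "ap": 1, "apc": 2, "es": 3, "esc": 4, "free_rider": 5}
_CONSULTING = frozenset((3, 4, 5))  # es, esc, free_rider keep live trust ledgers


def realize_damage(event: int, level: int, econ) -> float:
    """Residual damage of one citizen's choice under one realized severity.

    Light events damage no one.  Medium events damage only the uninvested
    (``med_damage``).  Critical events damage everyone: the full
    ``max_damage`` without investment, half of it with the medium investment,
    a quarter with the maximal one.
    """
    if event == 1:
        return 0.0
    if event == 2:
        return econ.med_damage if level == NONE else 0.0
    return econ.max_damage / (4.0, 2.0, 1.0)[2 - level]


def _damage_table(econ) -> tuple[tuple[float, float, float], ...]:
    """``table[event-1][level]`` — precomputed for the hot loop."""
    return tuple(
        tuple(realize_damage(ev, lvl, econ) for lvl in (NONE, MEDIUM, MAXIMAL))
        for ev in (1, 2, 3)
    )


def shared_damage(event: int, self_level: int, neighbor_levels, econ) -> float:
    """Damage borne by one member of a pooled neighborhood: the mean of the
    damages implied by every member's choice (self included)."""
    damages = [realize_damage(event, self_level, econ)]
    damages += [realize_damage(event, lvl, econ) for lvl in neighbor_levels]
    return sum(damages) / len(damages)


@dataclass
class Citizen:
    id: int
    x: int
    y: int
    quadrant: int
    profile: str
    capital: float
    avoided: float = 0.0
    trust: TrustLedger = field(default_factory=TrustLedger)
    n_follow: int = 0
    n_decisions: int = 0
    n_medium_events: int = 0
    n_medium_success: int = 0
    n_critical_events: int = 0
    n_critical_success: int = 0


@dataclass
class World:
    config: Config
    citizens: list[Citizen]
    neighbors: list[np.ndarray]  # same-quadrant citizen ids within social_radius
    authority: AuthorityState
    citizen_model: object
    authority_model: object
    prior: tuple[float, float, float]
    ap_level: int
    apc_level: int
    damage_table: tuple


def build_world(cfg: Config, rng) -> World:
    """Place the population and precompute everything static.

    Citizens are split evenly across the four quadrants and placed on
    uniformly random cells within their quadrant; profiles are assigned by the
    configured mix (floor allocation, remainder to the last listed profile)
    and shuffled so every quadrant sees every profile.
    """
    validate_config(cfg)
    profiles: list[str] = []
    for profile, count in profile_counts(cfg).items():
        profiles += [profile] * count
    profiles = [profiles[i] for i in rng.permutation(len(profiles))]

    half_w, half_h = cfg.world_width // 2, cfg.world_height // 2
    citizens = []
    for i, profile in enumerate(profiles):
        q = i % 4
        x = int(rng.integers(half_w)) + (q % 2) * half_w
        y = int(rng.integers(half_h)) + (q // 2) * half_h
        citizens.append(
            Citizen(id=i, x=x, y=y, quadrant=q, profile=profile,
                    capital=cfg.citizen_capital0)
        )

    r2 = cfg.social_radius**2
    neighbors = []
    for c in citizens:
        ids = [
            o.id
            for o in citizens
            if o.id != c.id
            and o.quadrant == c.quadrant
            and (o.x - c.x) ** 2 + (o.y - c.y) ** 2 <= r2
        ]
        neighbors.append(np.array(ids, dtype=np.intp))

    prior = cfg.events.as_tuple()
    ap_level = argmax_severity([p * 3 for p in prior]) - 1
    apc_level = argmin_cost_level(
        expected_costs_independent(prior, cfg.econ, cfg.policy, indication=None)
    )
    return World(
        config=cfg,
        citizens=citizens,
        neighbors=neighbors,
        authority=AuthorityState(capital=cfg.authority_capital0,
                                 capital0=cfg.authority_capital0),
        citizen_model=build_perception_model(cfg.citizen_sd),
        authority_model=build_perception_model(cfg.authority_sd),
        prior=prior,
        ap_level=ap_level,
        apc_level=apc_level,
        damage_table=_damage_table(cfg.econ),
    )


def step_event(world: World, rng) -> list[dict]:
    """One event: forecast, sequential decisions, realization, settlement,
    trust updates.  Returns one record dict per quadrant."""
    cfg = world.config
    econ = cfg.econ
    citizens = world.citizens
    n = len(citizens)
    interdependent = cfg.scenario == "interdependent"
    dmg_table = world.damage_table

    true_events = [
        int(rng.choice(3, p=world.prior)) + 1 for _ in range(4)
    ]
    forecasts: list[Forecast] = [
        forecast_from_pdf(perceive(ev, world.authority_model, rng))
        for ev in true_events
    ]

    order = rng.permutation(n)
    u_perceive = rng.random(n)
    u_random = rng.integers(0, 3, n)
    u_fine = rng.random(n)

    decisions = np.full(n, -1, dtype=np.intp)
    personal_pdfs: list = [None] * n
    social_pdfs: list = [None] * n
    cit_model = world.citizen_model
    cum = cit_model.confusion_cum
    reported = cit_model.reported_pdfs

    for i in order:
        c = citizens[i]
        code = PROFILE_CODES[c.profile]
        if code == 0:
            decisions[i] = u_random[i]
            continue
        if code == 1:
            decisions[i] = world.ap_level
            continue
        if code == 2:
            decisions[i] = world.apc_level
            continue
        # source-consulting citizens: es, esc, free_rider
        q = c.quadrant
        forecast = forecasts[q]
        row = cum[true_events[q] - 1]
        u = u_perceive[i]
        perceived = 1 if u < row[0] else (2 if u < row[1] else 3)
        personal = reported[perceived - 1]
        personal_pdfs[i] = personal
        counts = [0, 0, 0]
        for j in world.neighbors[i]:
            d = decisions[j]
            if d >= 0:
                counts[d] += 1
        social = social_pdf(counts)
        social_pdfs[i] = social

        if code == 5:  # free rider: never invests, still observes its sources
            decisions[i] = NONE
            continue

        trust = c.trust.trust
        ge = smooth_pdf(personal, trust["personal"])
        ge = aggregate(ge, smooth_pdf(forecast.pdf, trust["authority"]))
        if social is not None:
            ge = aggregate(ge, smooth_pdf(social, trust["social"]))
        probs = (ge[0] / 3.0, ge[1] / 3.0, ge[2] / 3.0)

        if code == 3:  # es: most probable event wins
            decisions[i] = argmax_severity(ge) - 1
        else:  # esc: expected-cost minimizer
            nbhd = (
                NeighborhoodContext(len(world.neighbors[i]), trust["social"])
                if interdependent
                else None
            )
            decisions[i] = decide(
                "esc", probs, econ, cfg.policy, cfg.scenario,
                nbhd=nbhd, indication=forecast.indicated_investment, rng=rng,
            )

    # -- realization & settlement ------------------------------------------
    own_damage = np.array(
        [dmg_table[true_events[c.quadrant] - 1][decisions[c.id]] for c in citizens]
    )
    if interdependent:
        damage = np.empty(n)
        for i, c in enumerate(citizens):
            nbrs = world.neighbors[i]
            damage[i] = (own_damage[i] + own_damage[nbrs].sum()) / (1 + len(nbrs))
    else:
        damage = own_damage

    fine_p = econ.fine_probability
    fines_on = cfg.policy in ("punitive", "punitive_and_encouraging")
    records = [
        {
            "quadrant": q,
            "severity": true_events[q],
            "indicated": forecasts[q].indicated_investment,
            "n_none": 0, "n_medium": 0, "n_maximal": 0,
            "damage": 0.0, "fines": 0.0, "incentives": 0.0,
        }
        for q in range(4)
    ]

    total_fines = 0.0
    total_incentives = 0.0
    for i, c in enumerate(citizens):
        q = c.quadrant
        ev = true_events[q]
        lvl = int(decisions[i])
        indication = forecasts[q].indicated_investment
        inv = investment_cost(lvl, econ)
        incentive = incentive_for(lvl, cfg.policy, econ)
        fine = 0.0
        if fines_on and indication > lvl and u_fine[i] < fine_p:
            fine = econ.fine_amount if lvl == NONE else econ.fine_amount / 2.0
        dmg = float(damage[i])
        c.capital += incentive - inv - fine - dmg
        avoided = dmg_table[ev - 1][NONE] - dmg
        c.avoided += avoided
        c.n_decisions += 1
        if lvl == indication:
            c.n_follow += 1
        if ev == 2:
            c.n_medium_events += 1
            if lvl >= MEDIUM:
                c.n_medium_success += 1
        elif ev == 3:
            c.n_critical_events += 1
            if lvl == MAXIMAL:
                c.n_critical_success += 1

        rec = records[q]
        rec["n_none" if lvl == NONE else "n_medium" if lvl == MEDIUM else "n_maximal"] += 1
        rec["damage"] += dmg
        rec["fines"] += fine
        rec["incentives"] += incentive
        total_fines += fine
        total_incentives += incentive

        if PROFILE_CODES[c.profile] in _CONSULTING:
            _update_trust(c, ev, lvl, inv + fine, dmg, avoided,
                          personal_pdfs[i], forecasts[q].pdf, social_pdfs[i],
                          dmg_table)

    settle_authority(
        world.authority, total_incentives, total_fines, float(damage.sum()),
        cfg.authority_damage_coeff,
    )
    return records


def _update_trust(c, ev, lvl, gross_cost, dmg, avoided,
                  personal, authority_pdf, social, dmg_table) -> None:
    """Revise the citizen's trust in each source it consulted this event.

    Performance is the probability the source's *raw* report assigned to the
    realized severity.  The evidence weight uses the episode's stake: the
    damage actually avoided when the citizen invested, or — when it did not
    invest but the source called for it — the damage it would have avoided by
    listening; the cost basis is gross (investment plus fine, before
    incentive), since the stake of the episode is what the citizen put down.
    """
    for kind, pdf in (("personal", personal), ("authority", authority_pdf),
                      ("social", social)):
        if pdf is None:
            continue
        indicated = argmax_severity(pdf)
        performance = pdf[ev - 1] / 3.0
        if indicated >= 2:
            if lvl > NONE:
                avoided_for_source = avoided
            else:
                # what listening to this source would have avoided
                avoided_for_source = (
                    dmg_table[ev - 1][NONE] - dmg_table[ev - 1][indicated - 1]
                )
            beta = experience_weight(True, avoided_for_source, dmg, gross_cost)
        else:
            beta = experience_weight(False, avoided, dmg, gross_cost)
        c.trust.update(kind, performance, beta)


@dataclass
class RunResult:
    """Per-run accounting: one entry per profile plus the authority's books."""

    seed: int
    profile_stats: dict[str, dict[str, float]]
    authority: dict[str, float]
    mean_trust: dict[str, float]
    event_rows: list[dict]


def run(cfg: Config, seed=None, collect_events: bool = True) -> RunResult:
    """Execute one run of ``cfg.n_events`` events and aggregate it."""
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    world = build_world(cfg, rng)
    rows: list[dict] = []
    for t in range(cfg.n_events):
        records = step_event(world, rng)
        if collect_events:
            for rec in records:
                rec["event"] = t
            rows.extend(records)

    stats: dict[str, dict[str, float]] = {}
    by_profile: dict[str, list[Citizen]] = {}
    for c in world.citizens:
        by_profile.setdefault(c.profile, []).append(c)
    for profile, members in by_profile.items():
        m = len(members)
        n_med = sum(c.n_medium_events for c in members)
        n_crit = sum(c.n_critical_events for c in members)
        n_dec = sum(c.n_decisions for c in members)
        stats[profile] = {
            "n": m,
            "capital": sum(c.capital for c in members) / m,
            "avoided": sum(c.avoided for c in members) / m,
            "follow_pct": 100.0 * sum(c.n_follow for c in members) / n_dec
            if n_dec else float("nan"),
            "success_medium_pct": 100.0 * sum(c.n_medium_success for c in members) / n_med
            if n_med else float("nan"),
            "cice_pct": 100.0 * sum(c.n_critical_success for c in members) / n_crit
            if n_crit else float("nan"),
        }
        stats[profile]["capital_plus_avoided"] = (
            stats[profile]["capital"] + stats[profile]["avoided"]
        )

    consulting = [c for c in world.citizens
                  if PROFILE_CODES[c.profile] in _CONSULTING]
    mean_trust = {}
    if consulting:
        for kind in beliefs.SOURCE_KINDS:
            mean_trust[kind] = sum(c.trust[kind] for c in consulting) / len(consulting)

    a = world.authority
    a.check_identity()
    return RunResult(
        seed=int(ss.entropy) if isinstance(ss.entropy, int) else -1,
        profile_stats=stats,
        authority={
            "capital": a.capital,
            "fines_collected": a.fines_collected,
            "incentives_paid": a.incentives_paid,
            "damage_borne": a.damage_borne,
        },
        mean_trust=mean_trust,
        event_rows=rows,
    )


@dataclass
class SummaryResult:
    config: Config
    runs: list[RunResult]


def replicate(cfg: Config, n_runs: int | None = None, seed: int | None = None,
              collect_events: bool = False) -> SummaryResult:
    """Independent replicate runs with deterministically derived child seeds."""
    if n_runs is None:
        n_runs = cfg.n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seed is None:
        seed = cfg.seed
    children = np.random.SeedSequence(seed).spawn(n_runs)
    return SummaryResult(
        config=cfg,
        runs=[run(cfg, seed=child, collect_events=collect_events)
              for child in children],
    )
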