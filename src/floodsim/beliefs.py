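"""Trust-weighted belief calculus over segmented severity densities.

All information exchanged in the simulation is a *segmented PDF*: a
piecewise-constant density over event severity on a unit support split into
``N_SEGMENTS`` equal segments (light, medium, critical).  A valid PDF has
non-negative segment densities summing to ``N_SEGMENTS`` (total area 1 with
segment width 1/N).  The probability of severity ``k`` is the integral of the
density over segment ``k``, i.e. ``d_k / N``.

A receiver does not consume a source's PDF raw: it first *smooths* it toward
the uniform density in proportion to its distrust of the source, then folds it
into its running global evidence by Bayesian (segment-wise product)
aggregation.  After the event realizes, the receiver scores the source by the
probability it had assigned to what actually happened and updates its trust by
a weighted mean whose evidence weight grows with the stakes of the episode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

N_SEGMENTS = 3

#: Uniform density — the neutral element of aggregation and the zero-trust
#: limit of smoothing.
FLAT: tuple[float, float, float] = (1.0, 1.0, 1.0)

#: Weight of the accumulated trust history in the trust-update weighted mean.
ALPHA = 10.0

#: Upper clamp for the evidence weight of a single episode.  The stake
#: formulas can exceed it (e.g. full damage plus a fine with zero cost), so
#: values are clamped rather than assumed in range.
BETA_MAX = 10.0

_PDF_TOL = 1e-9


def validate_pdf(pdf) -> tuple[float, float, float]:
    """Check the segmented-PDF invariant and return the PDF as a tuple.

    Raises ``ValueError`` on negative densities or total area != 1.
    """
    d = tuple(float(x) for x in pdf)
    if len(d) != N_SEGMENTS:
        raise ValueError(f"segmented PDF needs {N_SEGMENTS} segments, got {len(d)}")
    if any(x < -_PDF_TOL for x in d):
        raise ValueError(f"segment densities must be non-negative: {d}")
    if abs(sum(d) - N_SEGMENTS) > 1e-6:
        raise ValueError(f"segment densities must sum to {N_SEGMENTS}: {d}")
    return d


def smooth_pdf(pdf, trust: float) -> tuple[float, float, float]:
    """Shrink a source's PDF toward uniform in proportion to distrust.

    Each segment density ``d`` maps to ``1 + (d - 1) * trust`` and the result
    is rescaled to total area 1.  At ``trust=0`` the output is uniform (the
    source is ignored); at ``trust=1`` the PDF passes through unchanged.
    """
    if not 0.0 <= trust <= 1.0:
        raise ValueError(f"trust must be in [0, 1], got {trust}")
    smoothed = tuple(1.0 + (d - 1.0) * trust for d in pdf)
    total = sum(smoothed)
    return tuple(d * N_SEGMENTS / total for d in smoothed)


def aggregate(ge, info) -> tuple[float, float, float]:
    """Fold a source's (smoothed) PDF into the global evidence.

    Segment-wise product renormalized to total area 1 — Bayesian updating with
    the current evidence as prior.  Commutative, and associative up to
    renormalization; ``FLAT`` is neutral on either side.

    A product that vanishes on every segment (two sources each certain of a
    different severity) carries no usable evidence; the global evidence falls
    back to uniform with a warning.  This cannot arise from Gaussian-derived
    sources, whose densities are strictly positive.
    """
    prod = tuple(a * b for a, b in zip(ge, info))
    total = sum(prod)
    if total <= 0.0:
        log.warning("degenerate evidence: all-zero product of %r and %r", ge, info)
        return FLAT
    return tuple(d * N_SEGMENTS / total for d in prod)


def event_probabilities(pdf) -> tuple[float, float, float]:
    """Integrate the density over each segment: ``P(e_k) = d_k / N``."""
    return tuple(d / N_SEGMENTS for d in pdf)


def performance_of(reported, realized: int) -> float:
    """Score a source by the probability it assigned to the realized severity.

    ``reported`` is the source's *raw* PDF (pre-smoothing): the score compares
    what the source claimed with what happened, so the receiver's prior trust
    must not enter.  ``realized`` is the severity code in {1, 2, 3}.
    """
    return reported[realized - 1] / N_SEGMENTS


def experience_weight(
    source_indicated_invest: bool,
    avoided_damage: float,
    incurred_damage: float,
    incurred_cost: float,
) -> float:
    """Evidence weight of one episode for the trust update.

    The weight grows with the stake of the episode.  When the source's
    forecast called for investing (its most likely severity was medium or
    critical) the stake is the damage avoided thanks to it — or that would
    have been avoided by listening — net of the decision cost; when it
    forecast a light event the stake is the damage actually incurred, net of
    the cost.  Clamped to ``[0, BETA_MAX]``.
    """
    if min(avoided_damage, incurred_damage, incurred_cost) < 0:
        raise ValueError("damage and cost amounts must be non-negative")
    if source_indicated_invest:
        beta = abs(avoided_damage - incurred_cost)
    else:
        beta = abs(incurred_damage - incurred_cost)
    return min(beta, BETA_MAX)


def update_trust(t: float, performance: float, beta: float) -> float:
    """Weighted mean of the old trust and the episode performance.

    ``(ALPHA * t + beta * performance) / (ALPHA + beta)`` — a contraction
    toward ``performance``; with ``beta=0`` the trust is unchanged.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"trust must be in [0, 1], got {t}")
    if not 0.0 <= performance <= 1.0:
        raise ValueError(f"performance must be in [0, 1], got {performance}")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return (ALPHA * t + beta * performance) / (ALPHA + beta)


#: Source kinds a citizen keeps a trust entry for.
SOURCE_KINDS = ("personal", "authority", "social")


@dataclass
class TrustLedger:
    """Per-citizen trust toward each information-source kind.

    All entries start at 0.5 — maximal uncertainty between trust and
    distrust — and are revised by direct experience only.
    """

    trust: dict[str, float] = field(
        default_factory=lambda: {k: 0.5 for k in SOURCE_KINDS}
    )

    def __getitem__(self, kind: str) -> float:
        return self.trust[kind]

    def update(self, kind: str, performance: float, beta: float) -> None:
        self.trust[kind] = update_trust(self.trust[kind], performance, beta)
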