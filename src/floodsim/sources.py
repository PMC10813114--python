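"""The three information sources: personal judgment, authority forecast,
social observation.

Perception (both a citizen's own judgment and the authority's forecast
machinery) is a two-stage model.  First a *perceived* severity is drawn from a
3×3 confusion kernel conditioned on the true severity; then the reported
segmented PDF is the discretized truncated Gaussian centered on the perceived
severity with the perceiver's standard deviation, so the report's sharpest
segment is always the perceived severity and its peakedness reflects the
perceiver's precision.

The kernel's diagonal — the probability of perceiving the true severity — is
the calibrated accuracy.  The two published anchor points (sd 0.7 → 45%
accuracy for citizens, sd 0.5 → 70% for the authority) are not jointly
reproducible by any single naive Gaussian-argmax geometry, so accuracy is
treated as the primary calibrated quantity: it is linearly interpolated (and
extrapolated) through the anchors as a decreasing function of sd, and the sd
itself shapes the reported PDF and the adjacency weighting of errors
(a light event is misread as medium before critical, and symmetrically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.stats import norm

from .beliefs import N_SEGMENTS

#: Investment levels, ordered by protectiveness.  Severity code k maps to
#: level k-1: a light forecast calls for no investment, medium for the medium
#: investment, critical for the maximal one.
NONE, MEDIUM, MAXIMAL = 0, 1, 2
LEVELS = (NONE, MEDIUM, MAXIMAL)
LEVEL_NAMES = ("none", "medium", "maximal")

# Severity centers on the perception scale; segments span +-0.5 around each.
_CENTERS = (1.0, 2.0, 3.0)
_SUPPORT = (0.5, 3.5)

# Published calibration anchors: (sd, argmax accuracy).
_ANCHORS = ((0.5, 0.70), (0.7, 0.45))
_ACC_MIN, _ACC_MAX = 1.0 / 3.0, 0.999


def accuracy_from_sd(sd: float) -> float:
    """Map a perception sd to an argmax accuracy.

    Linear through the two anchor pairs, decreasing in sd, clipped to
    ``[1/3, 0.999]`` (chance level and a noiseless cap).
    """
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    (s0, a0), (s1, a1) = _ANCHORS
    acc = a0 + (sd - s0) * (a1 - a0) / (s1 - s0)
    return min(max(acc, _ACC_MIN), _ACC_MAX)


def _gaussian_segment_pdf(mean: float, sd: float) -> tuple[float, float, float]:
    """Discretize a Gaussian over the severity segments by the midpoint rule:
    evaluate the density at the three severity centers and normalize, returned
    as segment densities (masses × N).

    The midpoint discretization keeps the report sharply peaked on the
    perceived severity (the segment-integral alternative smears mass onto the
    neighbors and systematically depresses the performance a source earns when
    it is right, dragging long-run trust well below the source's accuracy).
    """
    masses = [norm.pdf(c, mean, sd) for c in _CENTERS]
    z = sum(masses)
    return tuple(m / z * N_SEGMENTS for m in masses)


@dataclass(frozen=True)
class PerceptionModel:
    """Calibrated perception of event severity.

    ``confusion[t-1]`` is the distribution of the perceived severity given
    true severity ``t``; its diagonal equals ``accuracy``.  ``reported_pdfs``
    caches the segmented PDF emitted for each perceived severity, and
    ``confusion_cum`` the row-wise cumulative sums used for inverse-CDF draws.
    """

    sd: float
    accuracy: float
    confusion: np.ndarray
    confusion_cum: np.ndarray
    reported_pdfs: tuple[tuple[float, float, float], ...]


def build_perception_model(sd: float) -> PerceptionModel:
    """Build the confusion kernel and report table for a given sd.

    Off-diagonal mass ``1 - accuracy`` in each row is split between the wrong
    severities with weights from a Gaussian of the given sd over the
    unit-spaced severity centers, so errors land on adjacent severities first.
    """
    acc = accuracy_from_sd(sd)
    confusion = np.empty((3, 3))
    for t in range(3):
        weights = np.array(
            [math.exp(-((k - t) ** 2) / (2.0 * sd * sd)) if k != t else 0.0
             for k in range(3)]
        )
        confusion[t] = weights / weights.sum() * (1.0 - acc)
        confusion[t, t] = acc
    reported = tuple(_gaussian_segment_pdf(c, sd) for c in _CENTERS)
    return PerceptionModel(
        sd=sd,
        accuracy=acc,
        confusion=confusion,
        confusion_cum=np.cumsum(confusion, axis=1),
        reported_pdfs=reported,
    )


def _draw_perceived(true_event: int, model: PerceptionModel, u: float) -> int:
    """Inverse-CDF draw of the perceived severity from the confusion row."""
    row = model.confusion_cum[true_event - 1]
    return 1 if u < row[0] else (2 if u < row[1] else 3)


def perceive(true_event: int, model: PerceptionModel, rng) -> tuple[float, float, float]:
    """One personal-judgment report: a segmented PDF whose sharpest segment
    is the (noisily) perceived severity."""
    return model.reported_pdfs[_draw_perceived(true_event, model, rng.random()) - 1]


def argmax_severity(pdf) -> int:
    """Severity with the highest density; ties break toward the more severe
    (conservative) reading."""
    best = 1
    for k in (2, 3):
        if pdf[k - 1] >= pdf[best - 1]:
            best = k
    return best


class Forecast(NamedTuple):
    """An authority forecast: the reported PDF plus the derived indication."""

    pdf: tuple[float, float, float]
    indicated_event: int
    indicated_investment: int  # level code: severity - 1


def forecast_from_pdf(pdf) -> Forecast:
    ev = argmax_severity(pdf)
    return Forecast(pdf=pdf, indicated_event=ev, indicated_investment=ev - 1)


def authority_forecast(true_event: int, model: PerceptionModel, rng) -> Forecast:
    """One forecast for one quadrant-event, shared by every citizen there."""
    return forecast_from_pdf(perceive(true_event, model, rng))


def social_pdf(neighbor_decisions) -> Optional[tuple[float, float, float]]:
    """Read the neighborhood's already-made decisions as a severity PDF.

    ``neighbor_decisions`` is a ``(n_none, n_medium, n_maximal)`` count
    triple; each decision level is read back as anticipation of the matching
    severity, so ``P(e_k)`` is proportional to the count at level ``k-1``.
    Returns ``None`` when no neighbor has decided yet — an absent source is
    simply skipped in aggregation.
    """
    total = sum(neighbor_decisions)
    if total == 0:
        return None
    return tuple(c / total * N_SEGMENTS for c in neighbor_decisions)
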