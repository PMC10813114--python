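# Methods

## Model overview

`floodsim` simulates a community of static citizens on a 32×32 toroidal
grid divided into four equal quadrants.  Quadrants are meteorologically
independent: every event draws one true severity per quadrant, i.i.d. across
events and quadrants, from a categorical distribution over {light, medium,
critical}.  There are no temporal dynamics within an event and no spatial
dynamics beyond the quadrant structure; an "event" is a single categorical
draw plus its economic consequences.

Citizens never observe the true severity before deciding.  They hold beliefs
as *segmented PDFs* — piecewise-constant densities over severity, one
segment per class, total area 1 (segment densities summing to 3).  Three
sources feed these beliefs:

1. **personal judgment** — a noisy perception of the incoming event;
2. **the authority's forecast** — one per quadrant per event, identical for
   every citizen in the quadrant;
3. **the social source** — the decisions already made by neighbors
   (same-quadrant citizens within the social radius), read back as severity
   anticipations (no investment ↦ light, medium ↦ medium, maximal ↦
   critical).  It is absent until at least one neighbor has decided.

Each source's report is smoothed toward the uniform density in proportion to
the citizen's distrust of it and folded into the citizen's evidence by a
segment-wise product (Bayesian aggregation from a flat prior).  Sources are
scored after every event by the probability their *raw* report assigned to
the realized severity — smoothing encodes the receiver's prior trust, not
the source's claim, so it must not affect the score — and trust is revised
by a weighted mean with fixed history weight α = 10 and an episode weight
β ∈ [0, 10] that scales with the stakes (damage avoided thanks to the
source, or incurred after a light forecast, net of the gross decision cost).

## Perception and its calibration

Perception is a two-stage model.  A *perceived* severity is first drawn from
a 3×3 confusion kernel conditioned on the truth; the emitted report is then
a Gaussian centered on the perceived severity with the perceiver's standard
deviation, discretized over the three segments.

The calibration constraint is that a perceiver with sd 0.7 identifies the
event in 45 % of cases and one with sd 0.5 in 70 %.  No single
Gaussian-argmax geometry reproduces both anchor pairs, so accuracy is the
primary calibrated quantity: it is linear in sd through the two anchors,
decreasing, clipped to [1/3, 0.999], and placed on the kernel diagonal.
Off-diagonal mass is split between the wrong severities with
Gaussian-of-the-same-sd adjacency weights, so a light event is misread as
medium long before critical, and symmetrically.  This guarantees the stated
accuracies by construction while the sd keeps shaping both the error
adjacency and the report's peakedness.

The report is discretized by the **midpoint rule** — the Gaussian density
evaluated at the three severity centers, normalized — rather than by segment
integrals.  The integral variant smears mass onto neighboring segments and
caps the score a source earns when it is *right* at ≈ 0.81 (authority) /
≈ 0.69 (citizen); long-run trust then settles well below the source's
accuracy, whereas the learned trust in the authority should hover near its
0.7 accuracy.  The midpoint rule keeps the correct-report score at ≈ 0.88
and moves long-run authority trust to ≈ 0.6–0.68 depending on the
population's decision mix, the closest a Gaussian-derived report family gets
to that anchor.  Report densities are strictly positive, so the degenerate
all-zero aggregation product cannot occur with these sources (if fed
hand-built one-hot PDFs, aggregation falls back to the flat density with a
warning).

## Decisions

The three investment levels cost 0 / 0.5 / 1 and imply the damage table
(rows = severity): light → 0/0/0; medium → 5/0/0; critical → 10/5/2.5.
Cost-reasoning profiles minimize expected total cost; exact ties resolve
toward the higher (safer) investment.  Profiles:

- `random` — uniform draw; the control group;
- `ap` — reacts to the modal prior event (light under the defaults ⇒ never
  invests);
- `apc` — minimizes expected cost on the prior; context-independent (always
  the medium investment under the defaults);
- `es` — most probable event of the aggregated evidence;
- `esc` — expected-cost minimizer on the aggregated evidence;
- `free_rider` (interdependent scenario only) — never invests but observes
  all sources and maintains trust like an `esc` citizen.

Two fine-term treatments coexist deliberately.  The ex-ante cost formulas
print unconditional expected-fine terms; the fine actually applies only when
the authority indicated a higher investment.  `apc`, which never consults
the authority, uses the printed unconditional terms; `es`/`esc`, who see the
indication, price a fine only where the current indication would produce one
(half fine for a medium investment under a critical indication, full fine
for no investment under any investing indication).  Under the default
economics both treatments yield the same argmin, so this choice does not
move the headline results.

Incentives are paid for *any* investment when incentives are active, not
only indicated ones — the reconstruction of the random/APC capital under the
encouraging authority (e.g. APC ≈ 100 − 100·(0.25 + 0.2325) ≈ 51.6) forces
this reading.

Under the interdependent scenario, realized damage is pooled: each member of
a neighborhood bears the mean of the damages implied by every member's
choice (own choice included), which matches the 1/(n+1) structure of the
interdependent cost formulas.  The cost system adds the expected damage
inflow from distrusted neighbors, CDFN = (MaxDamage/(n+1))·n·(1 − s) and
MDFN = CDFN/2, where s is the citizen's trust in the social source.

## The per-event loop

Per event: draw one severity and one authority forecast per quadrant; then
iterate all citizens in a fresh uniformly-random permutation.  Each citizen
consults its sources (the social source covering only already-decided
neighbors, so it grows progressively informative within the event), decides
irrevocably, and becomes visible to later deciders.  After all decisions:
realize damage (independent or pooled), pay incentives, assess fines
(independent Bernoulli detection per guilty citizen), settle the authority's
books, update trust ledgers and counters.

Avoided damage per citizen-event is the no-investment counterfactual minus
the realized damage, in both scenarios (under pooling the realized damage is
the neighborhood mean, which never exceeds the no-investment damage, so the
quantity stays non-negative).  For the trust update of a source that called
for investing while the citizen did not, the stake is the damage listening
would have avoided (counterfactual damage table difference at the source's
indicated level).

The authority's books: capital += fines − incentives − c·(total citizen
damage), with the damage-share coefficient c (default 0.5) exposed in the
configuration — no formula for the authority's own damage is available
beyond "it suffers from citizens' wrong choices", so it is parameterized;
0.5 reconciles the reported authority capital under the punitive policy
(≈ 18.4 k from 20 k) with the citizens' incurred-damage levels.  The
accounting identity capital = capital₀ + fines − incentives − damage borne
is asserted after every event.

## Randomness and reproducibility

One master seed; replicate runs receive child seeds through
`numpy.random.SeedSequence.spawn`, and a single generator drives each run in
a fixed program order (per-event vectors are pre-drawn for perception,
random-profile decisions and fine detection).  Runs are bit-reproducible
under a fixed seed; metrics consume no randomness, so adding instrumentation
cannot perturb trajectories.

## Defaults and parameters that matter

| parameter | default | meaning |
|---|---|---|
| event distribution | 77.91 / 17.44 / 4.65 % | historical alpine frequency triple |
| n_citizens | 200 | community size (50 per quadrant) |
| citizen_sd / authority_sd | 0.7 / 0.5 | perception noise ⇒ 45 % / 70 % accuracy |
| capitals | 100 / 20 000 | citizen / authority starting capital |
| investments | 1 / 0.5 | maximal / medium protective investment |
| damages | 10 / 5 | critical / medium damage to the uninvested |
| fine | 1 at 20 % detection | punitive instrument |
| incentive_rate | 0.5 | fraction of the investment refunded |
| social_radius | 3 cells | neighborhood radius (Euclidean, same quadrant) |
| n_events × n_runs | 100 × 100 | per-run length and replicate count |
| authority_damage_coeff | 0.5 | share of citizen damage borne by the authority |

Profile mixes are fractions; head-counts use floor allocation with the
remainder to the last listed profile.  Citizens are split evenly across
quadrants and placed on uniformly random cells.

## What the simulator emulates — and what it does not

The generator reproduces the study conditions above; it does not model
terrain or hydrology (the grid is abstract), communication channels
(sources are producers, not media), evacuation or movement, temporal
correlation between events, indirect or intangible damage, or irrational
and impulsive decision styles.  Agreement with the reference results
therefore shows that the decision-and-trust mechanism behaves as published
under those idealized conditions, not that it predicts any real
community's behavior.

## Problem sizes

Tests and the acceptance script run the full published scale — 100
replicate runs of 100 events with 200 citizens per experiment, and 100 000
draws for the perception calibration — since a replicate completes in
seconds (source-free profiles) to about half a minute (full source
machinery).  A handful of structural tests use smaller worlds (20–80
citizens) where only mechanics, not statistics, are under test.

## Known limitations

- The sd↔accuracy anchors are reconstructed, not derived: the confusion
  kernel and midpoint report are one defensible geometry among several.
  Quantities driven purely by the kernel (source-free profile economics,
  argmax accuracies, ES behavior) reproduce the reference values tightly;
  quantities sensitive to report peakedness near decision thresholds (the
  ESC decision mix, hence its follow-authority percentage and CICE, and the
  authority's capital under incentive-heavy policies) match as orderings
  but not cell-exactly.  In particular the ESC cost minimizer sits on a
  knife edge at P(e₃) ≈ 0.1 between the medium and maximal investment, and
  small perturbations of report shape move its mix between medium- and
  maximal-dominant regimes.
- Long-run authority trust lands at ≈ 0.6 (ES population) to ≈ 0.68 (ESC),
  short of the ≈ 0.7 anchor, because even a correct Gaussian-derived report
  cannot score a full 1.0.
- The social source reads precautionary investments as severity claims; in
  populations that over-protect, its measured performance (and hence social
  trust) collapses.  This is faithful to the decision-to-severity mapping
  but amplifies protective cascades within events.
- A single authority damage-share coefficient stands in for an unspecified
  relief-cost mechanism; authority-capital levels (not orderings) depend
  on it.
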