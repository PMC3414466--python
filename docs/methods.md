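# Methods

`seamount_ebsa` implements a semi-quantitative evaluation framework for
individual seamounts: how likely a seamount is to qualify as an
Ecologically or Biologically Significant Area (EBSA) under the Convention
on Biological Diversity criteria, how strongly it is threatened by fishing
and mining, how trustworthy the underlying evidence is, and which of four
conservation-portfolio categories it belongs to.  This note records the
model, its assumptions, the numerical conventions, and the design choices
made where the published procedure left the design open.

## EBSA likelihood score

Ten indicator slots stand in for the seven CBD criteria: four benthic
indicators of weight 3 (hydrothermal vent communities, macrophytes,
cold-water coral reefs/gardens, sponge aggregations), two benthopelagic
indicators (aggregating deep-sea fishes, weight 2; threatened bottom fishes
and sharks, weight 1), two pelagic OR-pairs (air-breathing visitors and
large visiting pelagics, each scored either as its threatened variant,
weight 2, or its plain variant, weight 1, never both), naturalness
(weight 1, meaning no known fishing or mining activity) and shallow summit
depth (above 800 m, weight 1, a productivity proxy).  A weight counts an
indicator once per CBD criterion it evidences.

With `W` the weight sum of the indicators present and `W_max = 21` the
maximum achievable sum (threatened variants of both pairs), the score is

    S = 1 + 4 W / W_max,      1 <= S <= 5,

categorised low for `S <= 3` and high for `S > 3`.  Because `W` is an
integer, the category is high exactly when `W >= 11`, which the test suite
verifies by enumerating all 2^8 x 3^2 = 2304 slot configurations.

Two conventions matter and both are forced by the published case-study
scores:

* **The denominator is fixed at `W_max = 21`** even when a plain pair
  variant is present or slots are data-deficient.  Any record-dependent
  denominator breaks at least one of the published scores (e.g. Condor
  3.48 with the plain air-breathing variant, Rosemary 2.52 with three
  data-deficient slots).
* **Data-deficient slots contribute 0 to `W`.**  The score is a likelihood
  given positive evidence; missing evidence is carried by the uncertainty
  index, not by the score.

Custom catalogs (different slots or weights) are supported; `W_max` is then
that catalog's maximum achievable sum.

## Threat score

Nine human activities are considered: bottom gillnetting, hook and line,
bottom and pelagic longlining, pots and traps, purse seining, bottom and
midwater trawling, and seafloor mineral extraction.  Each activity carries
an integer impact rating, 1 (very low) to 5 (very high), against each of
five ecological groups: physical habitat, habitat-forming corals and
sponges, groundfish, large pelagic fish, and air-breathing visitors.  For a
seamount with activity set `A`,

    TS = mean over groups g of  max_{a in A} M[a, g],

categorised none (`TS = 1`), low (`1 < TS <= 3`) or high (`TS > 3`).
Groups reached by no present activity contribute 1, not 0, so "no
activity" and "uniformly very-low impact" coincide at the scale's floor.
Data-deficient activities are treated as absent in `TS` (all eight
published case-study scores reproduce only under this reading) and enter
the uncertainty index instead.  Effort, catch and bycatch data are out of
scope: presence of a gear type is the only input, which makes the score
deliberately conservative.

## Reconstruction of the default impact matrix

The expert-elicited rating matrix itself is not published as numbers, but
nine of its consequences are: the eight case-study threat scores and the
statement that pelagic longlining alone yields `TS = 2.6`.  Each published
score is one exact constraint — the per-group maxima over the present
activity set must sum to five times the score — and `fit_impact_matrix`
solves this integer constraint system:

1. *Feasibility and a lexicographic incumbent* by depth-first backtracking
   over the cells (activity-major, group-minor), values tried in ascending
   order, with interval propagation: for every (constraint, group) pair the
   achievable maximum is bracketed from the assigned cells and the count of
   unassigned ones, and a branch dies when any constraint's achievable sum
   interval misses its target.
2. *The minimal total rating sum*, exactly: the constraints treat groups
   symmetrically, so every group's column draws on the same set of
   realizable per-group maxima vectors; all columns are enumerated once
   (5^8 for the default system), reduced to unique maxima vectors with
   their cheapest realizing column, and a small exact search picks one
   vector per group so the componentwise sums hit every target at minimal
   total mass.  For systems too large to enumerate, a branch-and-bound on
   the cells (pruned by the all-ones floor plus the largest per-constraint
   deficit) takes over.
3. *The canonical matrix*: the backtracking search re-run with the total
   fixed to that minimum; ascending-value DFS in cell order returns the
   lexicographically smallest such matrix first.

The canonical tie-break — minimal total sum, then lexicographic over
activities then groups — is a least-assumption rule: among all matrices
consistent with the published scores, ship the one positing no more impact
than those scores force.  The system is underdetermined (40 constrained
cells, 9 equality constraints), so the shipped matrix
(`data/default_impact_matrix.csv`) is one member of the feasible set, not
necessarily the original expert elicitation; it is a config file users can
replace with a region-specific matrix, which is validated at load.
Infeasible systems raise an error carrying a deletion-minimal
unsatisfiable constraint subset.  Mineral extraction appears in no
published activity set, so its row is a documented prior — (5, 5, 3, 1, 1):
very high on the physical habitat and on corals/sponges, medium on
groundfish, very low on the pelagic groups — rather than a solver output.
The solver is cross-checked against exhaustive enumeration on reduced
instances (up to 3 activities x 3 groups, ratings 1–3) in the test suite.

## Data-uncertainty index

Each scored observation carries an evidence grade: high (weight 0,
rigorous surveys), medium (0.5, incomplete or qualitative but
feature-specific information), or low (1, inferred or non-specific
information).  Per record and domain (10 indicator slots, or 9 activities),

    U = mean grade weight over scored slots + (data-deficient slots / total slots),

so `0 <= U <= 2`, with 0 for complete high-quality knowledge.  A pair slot
whose variants are both data-deficient counts once in numerator and
denominator (slot-based counting; member-based counting contradicts the
published values for Rosemary and Cobb).  When no slot at all is scored
the mean grade weight is defined as 1, so a fully unknown record attains
the limiting maximum `U = 2`.  Error bars are `score +/- U`, deliberately
unclipped (they may leave the 1–5 scale); the index is additive
bookkeeping of evidence, not a variance, and has no probabilistic
interpretation.

## Portfolio classification

Crossing the EBSA category with the threat category yields four cells —
low/low, low/high, high/low, high/high — with the threat category "none"
folded into the low-threat side.  High/low supports precautionary
protection of near-pristine valuable areas; high/high supports
protect-for-recovery strategies.  The per-seamount radar profiles expose
which parts of the ecosystem drive each score: the EBSA profile is
5 x (slots present / slots) per typology (benthic, benthopelagic, pelagic,
historical, geological), the threat profile is the per-group maximum
impact (1–5).

## Dummy-seamount simulator

`simulate_dummy_seamounts` draws hypothetical seamounts with each
indicator slot independently present with probability `p_indicator`
(default 0.5), a present pair slot threatened with probability
`p_threatened_variant` (default 0.5), and each activity present with
probability `p_threat` (default 0.5); all grades are high, since the
exercise probes the scoring geometry, not the uncertainty bookkeeping.
The original robustness experiment of this kind reported cell percentages
(5.1 / 3.6 / 36.2 / 55.1 over 1000 dummies) without stating its
randomization law; under independent Bernoulli(0.5) presences the exact
high-EBSA probability — computable by enumerating all slot configurations
(`exact_high_ebsa_probability`) — is about 0.46, inconsistent with the
60.2% high-EBSA total those percentages imply.  The published percentages
are therefore displayed here as the original result only and are not
reproduction targets; what the simulator is held to instead is the exact
enumeration: simulated high-EBSA fractions must sit within three standard
errors of the enumerated probability, and bounds/monotonicity must hold
across the full pattern space.  The simulator emulates configuration
randomness only — real seamount indicators are spatially and ecologically
correlated (e.g. corals and sponges co-occur), so passing these checks
validates the scoring machinery, not any ecological realism of the dummy
population.

## Numerical conventions and problem sizes

* Display rounding is half-up to 2 decimals (0.575 -> 0.58), applied to the
  float's shortest round-trip decimal representation so that sums of the
  decimal grade weights round as the exact decimals they stand for;
  comparisons in tests use a 0.01 absolute tolerance.  Raw full-precision
  values are kept alongside rounded ones in the result JSON.  One
  published value (Josephine's threat uncertainty, printed 1.16) computes
  to 1.1667 = 5/6 + 3/9; the printed value appears to round intermediate
  terms, and the 0.01 tolerance absorbs the difference.
* Categories are assigned from unrounded scores.
* Exhaustive checks enumerate all 2304 indicator configurations; simulator
  checks use n = 1000 draws at three-standard-error tolerances with fixed
  seeds; solver cross-checks enumerate reduced instances (<= 3^9 matrices
  each).  The default matrix reconstruction solves in a few seconds.
* One published fixture is internally inconsistent: Sedlo has naturalness
  present alongside a present pelagic-longline fishery, contradicting the
  naturalness definition.  The record is preserved verbatim; validation
  reports a warning, not an error.

## Known limitations

* The reconstructed impact matrix is a canonical feasible solution, not
  the original elicitation; per-cell values should not be interpreted
  individually, only through the scores they produce.
* Presence/absence inputs cannot distinguish intensity of use; threat
  scores saturate quickly as activities accumulate.
* No spatial or temporal dynamics: indicators and activities are treated
  as static attributes of a feature.
* Climate change and pollution are not modelled as threats; endemism is
  not a scored indicator.
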