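# Methods

## The assay being modelled

The package computes the readout of a plate-based ex vivo drug-sensitivity
screen for primary AML. Each well contains ~50,000 mononuclear cells over a
GFP⁺ stromal feeder layer; after 72 h of drug exposure the well is stained
with a six-marker panel and acquired on a cytometer. The analysis problem
is: from one event table per well, count viable cells per biological
compartment (lymphocytes; leukemic bulk split into GPR56⁺/Diff⁻
stem-enriched "LSC", GPR56⁻/Diff⁺ differentiating "DIFF", GPR56⁻/Diff⁻
basal, and GPR56⁺/Diff⁺ double-positive states), normalize treated counts
to same-sample DMSO vehicle wells, integrate dose-response profiles into a
single activity score per drug and readout, and feed those scores into
decision statistics.

## Synthetic data generator

Because raw screen data are not publicly deposited, the generator is a
first-class, tested component that defines the conditions under which every
downstream guarantee is demonstrated.

**Composition.** A well draws its events from a multinomial over
{stroma, lymphocyte, LSC, DIFF, basal, dead} with default viable fractions
(0.05, 0.10, 0.08, 0.12, 0.55) and the remaining 0.10 dead at baseline —
a plausible mononuclear-cell composition for a stroma-co-cultured AML
sample; the exact split is a modelling choice, not a measured constant.
Seeding defaults to 50,000 cells per well.

**Drug action.** Each drug carries per-population Hill survival models
s(c) = 1 − E·cʰ/(cʰ + EC₅₀ʰ) with E ∈ [0,1], EC₅₀ > 0, h > 0, and
optionally a differentiation-induction Hill model that moves basal and LSC
events into the Diff⁺ state *before* survival is applied (transitioning LSC
events keep GPR56 with a configurable retention probability, default 0, so
double positives arise only through that route). Killed cells join the dead
pool, so viable + dead = seeded exactly (an invariant the tests assert).
Closed-form expected counts (`expected_viable_fractions`) mirror the
stochastic sampler step for step and serve as the analytic oracle in
recovery tests.

**Intensities.** Post-compensation log₁₀ intensities, two Gaussian
components per channel (negative mean 1.0, positive mean 3.0, SD 0.25 by
default — each component mean 4 SD from the midpoint decision boundary).
No spillover, doublets, debris or acquisition drift are modelled: passing
recovery tests therefore demonstrates correctness of the gating logic and
thresholds under clean mixtures, not robustness to instrument artefacts.
The dead-cell stain is *positive* in dead events; dead events otherwise
keep their source population's marker profile.

**Noise and seeds.** Technical replicate noise is a per-well multiplicative
log-normal factor on the seeding count (CV 10% by default, mean 1). All
randomness flows from one integer seed: `simulate_plate` builds a
`SeedSequence` and spawns one child per well in layout order, so plates are
bit-reproducible and wells are independent streams. The number of acquired
events per well is a parameter (`acquired_fraction`, default 1.0) rather
than an assumed constant.

## Gating

Thresholds are estimated per channel from pooled vehicle-well events: a
two-component 1-D Gaussian mixture fitted by EM with deterministic
initialization (component means at the 25th/75th percentiles, pooled
variance, equal weights), cut at the equal-posterior point between the
component means (the root of a quadratic; fallback to the mean midpoint if
no root is bracketed). The EM is hand-written (~40 lines) because the
determinism contract — fixed quantile initialization, no random restarts —
is part of the module's interface. A BIC comparison against a single
Gaussian rejects channels with no real positive population (e.g. GPR56 in a
sample without GPR56⁺ cells); such channels require a manual override,
which always wins and is recorded with provenance `"configured"` in the
thresholds JSON audit trail.

The hierarchy is fixed: viability (events **above** the cutoff are dead,
since the fixable stain labels dead cells) → GFP (above = stroma, excluded)
→ lymphocyte dump channel (above = lymphocyte) → GPR56 × Diff quadrants on
the remaining bulk. CD45 is carried in the panel but not used as a decision
node by default (synthetic wells contain no debris); an optional CD45⁺ gate
before the lymphocyte split is exposed. Double positives are counted inside
bulk but excluded from both LSC and DIFF, matching the strict state
definitions. Every viable GFP⁻ event lands in exactly one terminal
population; `WellCounts` enforces the partition identities at construction.

## Normalization

Treated counts are divided by the arithmetic mean (configurable to median)
of the same sample's vehicle wells. Within-bulk proportions (%LSC, %DIFF)
are computed from raw counts and reported unnormalized — whether heatmap
proportions should be vehicle-scaled is ambiguous in the assay description;
raw was chosen and the pattern module owns display scaling. A zero vehicle
mean flags that readout unusable without killing the others; a sample with
no vehicle wells is a hard error. Replicates stay separate until
`summarize_replicates` (mean ± sample SD; single wells flagged, SD 0).

## Activity scoring

AOC integrates 1 − v(x) trapezoidally over x = log₁₀(c) affinely rescaled
to [0, 1]. Rescaling makes scores comparable across drugs with different
dose ranges; the raw-log-width alternative is exposed (`rescale=False`)
since the convention is not recoverable from the assay description.
"Untruncated" means exactly that: neither v nor the result is clipped, and
negative AOC is a legal output signalling net outgrowth. Replicates are
averaged before integration (configurable order was considered and
rejected: averaging v then integrating equals averaging per-replicate AOCs
for a shared dose grid, and profiles here always share the grid, so the
default is also the cheap choice). Degenerate inputs — fewer than 2 doses,
non-ascending or non-positive concentrations, non-finite values — are
rejected at profile construction.

Screening concentrations: ICₓ is found by linear interpolation of v against
log₁₀(c) in the first bracketing dose interval of a healthy-CD34⁺ profile
(error naming the level if unbracketed); the maximal screening dose is
min(Cmax, IC₄₀) and the fixed low dose for third agents is
min(0.2·Cmax, IC₁₀), with units checked between the PK table and the
profile.

## Pattern classification

The drugs × (BULK, %LSC, %DIFF) matrix is standardized per column with
sample SD after negating BULK and %LSC, so larger always means more active.
Constant columns map to zeros with a flag. Clustering is agglomerative
(Ward, Euclidean) cut at k = 3 — linkage, metric and k are conventions, all
configurable; rows are processed in sorted drug-id order so labels are
independent of input order. Clusters are labelled by centroid argmax
(BULK → cytotoxic, %LSC → stemness-specific, %DIFF → differentiating), with
ties broken in that priority order and label collisions resolved by giving
the contested label to the cluster with the larger coordinate. A rule-based
fallback (`classify_activity`: argmax with an "inactive" band) covers
single-drug queries where clustering is undefined.

## Decision statistics

- **Chemosensitivity**: sensitive ⇔ AOC(population) > AOC(lymphocytes) on
  the same dose series; equality is resistant. The call is invariant to
  adding a constant to both scores.
- **Combination benefit**: per agent, deltas = AOC(triplet) − AOC(backbone)
  per patient; one-sample two-sided t test against 0 (equivalent to a
  paired two-sample test on the triplet/backbone scores); BH correction
  across agents. Agents observed in fewer than 3 patients are reported
  without p/q; zero-variance deltas are flagged degenerate rather than
  given a fabricated p.
- **Nomination**: per patient, argmax delta on the LSC readout; all deltas
  ≤ 0 → "no benefit"; exact ties → lexicographically smallest agent id,
  flagged.
- **Fisher exact 2×2**: two-sided by summing hypergeometric probabilities
  of all fixed-margin tables no more probable than the observed one. The
  enumeration runs in exact integer arithmetic (comparing integer
  numerators over the common denominator C(n, c₁)), so probability ties on
  the opposite tail are handled without a floating tolerance. Two-sided was
  chosen because it reproduces the printed p = 0.08 on the published
  remission table.
- **Mann–Whitney**: exact enumeration when min(n) ≤ 8 with tie-free data,
  tie-corrected normal approximation (with continuity correction)
  otherwise; the method used is recorded.
- **BH FDR**: step-up with monotonicity enforcement (via statsmodels),
  q ≥ p elementwise, permutation-consistent.
- **Chemogenomic scan**: Mann–Whitney of AOC by mutation status per
  (treatment, gene, readout), BH across the scan, pairs with < 3 patients
  per genotype skipped and listed.

## Problem sizes and simulation design

Recovery studies run at sizes chosen to give stable rates while staying
cheap: gating recovery uses 50 wells × ~10,000 events (accuracy is
event-count dominated, and 500k events already pins the rate to ±0.01%);
archetype recovery uses 100 independent 15-drug simulations; benefit
recovery uses 100 screens of 20 patients × 23 agents plus 100 effect-free
screens for the null. The readout-level simulators
(`simulate_archetype_readouts`, `simulate_benefit_screen`) sample from the
generator's closed-form expectation models with replicate noise rather than
at event level — the quantities under test (clustering, AOC integration,
t/BH machinery) consume readouts, and event-level fidelity is covered
separately by the gating recovery study. In the benefit screen, noise
(SD 0.1) is applied to each normalized value and averaged over technical
triplicates before AOC integration, mirroring the plate design.

## Known limitations

- The mixture-threshold gating assumes roughly two log-normal components
  per channel; skewed or >2-component real channels need overrides.
- No compensation/spillover, doublet discrimination, edge-well correction
  or acquisition-drift handling: upstream QC is assumed done.
- The generator's state transitions are instantaneous fractions at fixed
  exposure time; no kinetics.
- Survival modelling (event-free survival, Cox regression) and
  mixed-effects modelling of culture-condition contributions are out of
  scope; clinical covariates pass through untouched.
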