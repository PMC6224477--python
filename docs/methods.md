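# Methods

## Collision race model

The race treats one trailing/leading ribosome pair in isolation. The
trailing ribosome draws a single velocity `V` and holds it while closing
the inter-ribosomal distance `IRD` (P-site to P-site, codons); the lead
advances independently at `v_lead`. The pair collides iff the lead's
advance during the closure time `IRD/V` is less than the escape distance.

* **Velocity family.** "Mean ± SD" elongation-rate summaries are read as a
  normal truncated at zero and renormalized — the simplest strictly
  positive family consistent with a two-moment summary. Defaults: mean
  5.6 codons/s, SD 2.5 codons/s. With SD = 0 the model degenerates to a
  point mass and the collision probability becomes a step function at the
  deterministic threshold `v* = escape · v̄ / IRD`.
* **Geometry.** The collided P-site separation (`footprint_codons`,
  default 10) is a parameter; structural evidence can be read as 9 or ~10
  codons depending on how the inter-ribosomal register is counted, and the
  default follows the 10-codon convention used for the whole-number escape
  distance of 11. The escape distance is always `footprint + 1`.
* **Ties.** An advance of exactly the escape distance counts as escape:
  reaching 11 codons is enough. Because the advance criterion `a ≥ 11` is
  equivalent for real-valued `a` to `floor(a) ≥ 11`, no discretisation of
  the Monte-Carlo advance is needed and analytic and sampled estimates
  target the same quantity.
* **One-shot race.** The race ends when the trailing ribosome has covered
  the *initial* IRD; there is no continuous pursuit with relative-velocity
  closure and no within-closure velocity fluctuation. This is the cheapest
  model that yields the threshold algebra above; a pursuit model would
  shift probabilities near the threshold but not the threshold itself.
* **Closure time.** `closure_time` returns the exact quotient `IRD/v`
  (66/5.6 = 11.79 s at defaults); no rounded constant is stored.

The heatmap parameterises the x axis as absolute lead velocity, with
`velocity_for_fold`/`fold_for_velocity` converting to fold-slowdown of the
trailing mean; default grids (IRD 10–200 codons, lead velocity
0.1–5.6 codons/s) are presentational only.

## Traffic simulator

Continuous-time, exact, event-driven (exponential waiting times, one event
per iteration; propensities rebuilt from state each iteration). Codons are
1-based; a ribosome at codon `p` steps to `p+1` at the codon's rate unless
a leading neighbour sits at `p + footprint`; a pair at a gap of exactly
`footprint` is *collided* (the flag is positional and clears if the gap
reopens; a sticky variant, `allow_collided_resume=False`, models steric
trapping of the collided ribosome). Initiation places a ribosome at codon
1 whenever no ribosome occupies codons 1–footprint; termination removes a
ribosome from the last codon at `termination_rate` (0 models a trapped
termination complex). Determinism: one PCG64 generator seeded from
`params.seed` drives every draw, and candidate events are enumerated in a
fixed order (initiation, then per-ribosome 3'→5': step, ubiquitination,
commitment, then resolution), so identical inputs give bit-identical
event logs; continuous event times make true ties measure-zero.

**Drug regimes.** Stochastic arrest: after onset, each completed step
arrests the ribosome with probability `q` (default 0.002/step), permanently
— arrested ribosomes become roadblocks that trailing ribosomes queue
behind. Global arrest: every ribosome (including any that initiates later)
arrests at onset, freezing spacings as they were. Resumable slow regions
(rate overrides) and irreversible drug arrest are deliberately distinct
mechanisms.

**Quality control.** Only the trailing member of a collided interface is
ever ubiquitinated (`k_ub`, default 0.1/s, requires the sensor), matching
the interface asymmetry of the modification sites; the queue lead is never
marked, so an isolated queue of `n` saturates at `(n−1)/n` marked.
"Commitment" (`k_commit`, 0.05/s) of a ribosome whose marked collided
partner trails it abstracts the unknown downstream step that stops further
elongation; a committed ribosome plus the collided run behind it is
removed at `k_res` (0.01/s). The rate defaults are chosen to separate the
regimes at the simulated scales (seconds-to-minutes, single transcripts),
not fitted to measurements. Sensor knock-out (`sensor_present=False`)
forces `k_ub = 0`, which silences the whole cascade.

**Read-through assay.** Every ribosome that steps into the slow region is
scored by its fate: read-through (steps past the 3' edge), removed
(resolution first), or censored at `t_max`; the reported fraction is
readthrough/(readthrough+removed), a stochastic stand-in for a
dual-fluorescence stall-reporter ratio. The default assay transcript is a
scaled reporter (150 codons, 21-codon slow region at codons 61–81 at
0.2 codons/s) so that 4 initiation rates × 500 mRNAs complete in about a
minute; the full-length 550-codon reporter preset behaves the same way at
proportionally higher cost.

## Initiation-rate calibration

A freshly initiated ribosome occludes initiation until its P site clears
the footprint, so consecutive initiations are separated on average by
`footprint/v̄ + 1/α` and the realised downstream spacing is v̄ times that
headway. Presets therefore use `α = v̄/(spacing − footprint)` — 0.1/s for
the 66-codon genome-average spacing, 0.31/s for the 28-codon dense regime
— rather than the naive `v̄/spacing`, which under-fills by the initiation
dead time (~15% at 66 codons). The simulated steady-state spacing then
matches the target within the ~10% accuracy of the renewal argument, and
the dense 140-codon preset carries 4–6 ribosomes on average.

## Digestion model

Each ribosome protects 4 codons 5' and 5 codons 3' of its P-site codon
(30 nt total; codon `c` spans nt `3c−2..3c`, protections clipped at
transcript ends). These nt-level numbers are internal conventions chosen
so that neighbours at the 10-codon collided gap abut with zero exposed
linker, consistent with full shielding of the inter-ribosomal mRNA in the
collided structure. An exposed linker shorter than 3 nt (one codon) is
uncuttable and merges the flanking protections, so gap = footprint merges
into a multimer fragment and gap = footprint + 1 is already cut — the
sharpest threshold that still collapses loosely packed polysomes to
monosome footprints. Fragment classes (ribosomes spanned) are the proxy for
gradient multimer peaks; no sedimentation physics is modelled.

## What the synthetic presets do and do not emulate

Presets reproduce the *kinetic regimes* of the benchmark experiments —
free flow at genome-average or dense spacing, a trapped termination
complex, low/high-dose irreversible elongation inhibition, a mid-ORF
stall reporter — on a single mRNA with uniform base rates. They do not
model codon-specific velocity maps, subunit-level states, competing mRNAs,
nascent-chain degradation, or nuclease sequence bias. Consequently,
passing tests show internal consistency of the collision/queue/QC logic
and agreement with the race algebra, not agreement with any particular
profiling dataset. Transcript lengths for the generic presets (600 codons
genome-average, 300 codons for the stop-codon stall) are presentational
choices; simulated horizons (t_max 400–600 s) and replicate counts
(20–200 seeds, 500 mRNAs per assay point) are sized so the full suite
runs in a few minutes on one core.

## Numerical and degenerate-input conventions

* Probabilities are computed from `scipy.stats.truncnorm` survival
  functions; no hand-rolled tail approximations.
* A lead velocity of 0 gives collision probability exactly 1 (the
  truncated velocity distribution has strictly positive support).
* Empty snapshots digest to an empty profile; a trajectory window with
  fewer than two ribosomes reports spacing as NaN rather than raising.
* Snapshots taken at an event's exact timestamp reflect the pre-event
  state (left-continuous sampling).
* Monte-Carlo collision estimates require an explicit seed; omitting it
  is an error, not a silent nondeterminism.

## Known limitations

* The one-shot race underestimates collision probability for leads only
  slightly faster than the threshold (a real pursuit continues after the
  trailing ribosome covers the initial IRD).
* Queue resolution removes a committed ribosome with the collided run
  behind it; any ribosome ahead of the committed one survives. Whether
  commitment requires the *immediate* marked partner (the rule used) or
  any marked queue member is a modelling decision.
* Per-step Bernoulli drug arrest makes run length geometric; real
  inhibitor kinetics are concentration- and time-dependent.
* Initiation can occur the instant the 5' region clears, so a small
  fraction of pairs is born at exactly the collided gap; frozen free-flow
  snapshots therefore retain a few percent of disome-protected fragments,
  consistent with the observation that native polysomes contain occasional
  stochastically collided di-ribosomes.
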