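# Methods

## Scope and model structure

`poolpcr` models real-time PCR on a pool of 60-mers whose central 20
positions are (partially) degenerate. The pool is never tracked per
sequence — a fully degenerate 20-mer region has 4^20 members — but as a
histogram of duplex classes indexed by mismatch count `m`, which is exact
under exchangeability: every member has the same marginal behavior, and
only the pairing statistics enter the readout.

### Library combinatorics

A library spec is a list of per-position base subsets. Diversity is the
exact big-integer product of subset sizes. The mismatch count of two
independent uniform draws is Poisson-binomial with per-position mismatch
probability `1 − 1/|alphabet_i|`; the pmf is computed by convolution (exact
to double precision at L ≤ 40). The `m = 0` event coincides with the two
draws being identical, so the mismatched-pair law is this pmf conditioned
on `m ≥ 1`. Biased primers fix the leading `k` variable positions; the
amplifiable fraction is the exact rational product of per-position overlap
fractions, so an extension matching a fixed prefix costs nothing and an
extension into fully degenerate positions selects `4^-k` of the pool.

### Code-set design

Sublibrary barcodes need pairwise Hamming distance ≥ 16 at length 20. That
sits near the quaternary Plotkin bound (≤ 16 codewords), which is checked
first and returned as a hard infeasibility when violated. Construction is
seeded randomized greedy accumulation with targeted repair: a uniform
random candidate is hill-climbed — while it is too close to an accepted
codeword, one agreeing position is re-randomized — until it satisfies the
constraint. Plain accept/reject sampling stalls at this density (the
acceptance probability against nine accepted words is ~10^-4 and worsens
with correlation); the repair walk reaches ten words in a few thousand
steps for every seed tried. The returned minimum distance is always
recomputed from the members.

### Thermal and dye model

The paper-level facts to reproduce are ordinal: signal is strongly
diminished for `m ≥ 10` with a further drop beyond `m ≥ 14`; a few
mismatches cost almost nothing; elongating at 74 °C spreads low-diversity
pools apart while 68 °C spreads high-diversity pools. A two-parameter
linear melting model with a logistic transition is the simplest form with
those properties:

| parameter | default | meaning |
|---|---|---|
| `tm_full` | 82 °C | Tm of the perfect 60-bp duplex |
| `delta_tm_per_mismatch` | 1.2 °C | linear Tm penalty per mismatch |
| `transition_width` | 2.5 °C | logistic helix–coil width |
| `t_elongation` | 72 °C | readout temperature |

The dye factor is the bound fraction at the readout temperature normalized
to a perfect duplex at the default elongation temperature, clamped to
[0, 1]. No nearest-neighbor thermodynamics, salt correction, or dye
photophysics is attempted; the four values are config-exposed.

The functional factor `F(m)` is a monotone PCHIP interpolation through
`(0, 1.0)`, `(7.5, 0.5)`, `(15, 0.1)`, clamped beyond the last anchor. The
anchor abscissae are the mean pairwise mismatch counts of 10- and
20-position fully degenerate libraries; i.e., the library-level F values
are read as F evaluated at the library's mean random-pair mismatch count.
Pool F is the concentration-weighted mean over full-length duplex classes.

### The cycle model

Annealing is a single competitive partner choice per strand per cycle: a
sense strand takes primer B′ with probability `P_B/(P_B + T)` and a random
antisense strand otherwise (symmetrically for antisense). No partial
hybridization kinetics are modeled; this one mechanism already produces
every observed curve class. A strand–strand pairing is perfectly matched
with probability `min(1, 1/N_eff + ε)`:

* `N_eff` = diversity for degenerate libraries, member count for uniform
  code sets, inverse Simpson index for weighted pools;
* `ε` (re-equilibration bias) defaults to 0 for degenerate libraries and
  0.2 for code sets. A ten-member code set needs a visibly intermediate
  curve — annealing of a few discrete species partially re-equilibrates
  toward perfect duplexes — while `ε = 0.2` still leaves 70% of pairings
  mismatched, far from perfect matching. With the shipped thermal defaults,
  smaller biases (≤ 0.15) leave the code-set curve in the peaked class.

Extension converts primer hybrids into perfect duplexes with efficiency
0.95, consuming primer one-for-one with created strands (an exact
conservation law, tested). Unextended primer hybrids are 20-bp stubs and
are ignored in the fluorescence sum. Fluorescence is normalized to the
plateau of a diversity-1 reference run under identical conditions, so 1.0
means "classic qPCR plateau".

Default run grid: 45 cycles, 50 nM primers, 100 pM template. Primer
concentration is kept in the regime where endpoint signal responds linearly
to primer amount; the config treats this as a bound, not a model.

The **turning point** of pool F is reported as the first cycle whose F drop
exceeds a sensitivity (default 0.02 per cycle). A literal "first negative
difference" is degenerate here: in the deterministic recursion F declines
by ~10^-3 per cycle from cycle 1, and the meaningful event — synthesis of
perfect duplexes no longer offsetting reshuffling — is the knee of the
curve, which the sensitivity threshold locates a few cycles before primer
exhaustion.

**Finite-copy mode** replaces expectations by binomial/multinomial draws on
integer molecule counts (template copies set by `initial_copies`, primers
scaled proportionally) and converges to the deterministic trajectory as
copy number grows (tested at 200 vs 200 000 copies).

**Network-extension mode** encodes the hypothesis that late-cycle diverse
pools grow into multi-strand, high-molecular-weight networks: each cycle a
fraction `network_rate × (1 − 1/N_eff) × T/(P_B + T)` of mismatched
pairings with partially overlapping 3′-recessed ends is extended, summing
the two partners' lengths; the strand-length histogram (capped at 64 units)
and the excess mass feed an aggregate fluorescence term with unit dye
factor (interwoven networks bind dye strongly). This mode is qualitative
by design — it reproduces "no long products for a single sequence, heavy
tails and fluorescence reoccurrence for diverse pools after 45 cycles" —
and is implemented for the deterministic mode only.

### Selection models

*Restriction digestion.* The two-sublibrary mixture (each with a fixed 6-nt
site inside a 14-position degenerate region) is simulated with labeled
pairing components: same-sublibrary pairs share their site as a perfect
homoduplex (cuttable), cross pairs carry a site/site heteroduplex (not
cuttable by either enzyme) and 6 extra mismatches. Cut probability is
`0.9 × exp(−m/3)` when both strands carry an active enzyme's site. The
`exp(−m/κ)` protection form is a modeling choice (the mechanism by which
flanking mismatches protect a matched site is asserted, not measured);
κ = 3 makes 5-cycle pools (mostly `m = 0`) strongly cut and 25-cycle pools
(`m ≈ 10` and above) protected to within a few percent.

*DECL capture.* Members are tagged strong (biotin), weak (iminobiotin), or
untagged; retention after `w` washes is `capture(tag) × retention(tag)^w`.
Defaults — strong 0.95/0.95, weak 0.5/0.15, untagged 0.08/0.05 — are
phenomenological, chosen once so the four scenario libraries reproduce the
full set of qualitative selection outcomes (most DNA captured by the
1-strong+9-weak library after one wash, the 1-weak library least enriched,
two washes leaving the strong-binder libraries essentially monocomponent
at inverse-Simpson < 1.5 while the all-weak library stays a uniform
10-member mixture). They are not measured affinities and are
config-exposed. The eluted abundance vector can be fed back into the
simulator as a weighted code-set pool.

### Inverse estimation

Feature extraction: Ct by linear interpolation at a threshold of 0.1
(relative to the reference plateau; standard qPCR practice), endpoint, peak
height/cycle, decline ratio `(peak − endpoint)/peak`, and a shape class
with fixed cutpoints 0.1/0.5 on the decline ratio (the cutpoints are
arbitrary but documented; tests rely on orderings, not the cutpoints).
The calibration bank simulates a (diversity 4^n, concentration) grid;
estimation is nearest-neighbor in z-scored (Ct, endpoint, decline) space
with ties broken toward lower diversity and an extrapolation flag outside
the bank hull. The quantitative estimator is this package's
operationalization of the curve readout — the underlying experiments
establish that curves shift with concentration and reshape with diversity,
not a specific inversion procedure.

## What the synthetic conditions do and do not show

All tests run on synthetic libraries generated by `poolpcr.fixtures` at the
default bench condition. The fixtures reproduce stated design properties
(diversities, layouts, code distances, tag scenarios), not literal bench
sequences; primer and filler 20-mers are synthetic stand-ins. Equal-diversity
layouts with different per-position alphabet sizes have slightly different
pairwise mismatch laws (twenty 2-base positions average 10 mismatches per
random pair, ten 4-base positions 7.5), so their curves are similar but not
identical. Passing tests show the model reproduces the full ordinal
phenomenology and is internally consistent; they do not calibrate absolute
fluorescence, real enzyme kinetics, or bead-binding affinities, and
sequence-composition biases (GC content, secondary structure, synthesis
bias) are out of scope throughout.

## Problem sizes

The suite and the acceptance script use: exhaustive oracles up to diversity
4^6; Monte-Carlo mismatch sampling at 10^5 pairs; 45-cycle deterministic
simulations (each with its diversity-1 normalization run); a 10 × 4
calibration bank with 60 random-query recoveries; and finite-copy runs at
2 × 10^2 and 2 × 10^5 template copies. Everything is seeded; deterministic
runs are bit-reproducible.
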