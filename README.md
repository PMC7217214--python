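# poolpcr

Simulation and curve analysis of real-time PCR (qPCR) on large,
heterogeneous degenerate DNA libraries.

## The problem

A degenerate oligonucleotide library such as `A-N20-B` — a 20-nt fully
randomized region flanked by two fixed 20-nt primer regions — contains
4^20 ≈ 1.1 × 10^12 distinct sequences; a 10 µL sample at 1 nM holds roughly
one molecule of each. No sequencing run gives a quick readout of how diverse
such a pool is, yet that readout is exactly what selection workflows (SELEX
rounds, DNA-encoded chemical library pulldowns) need between steps.

Real-time PCR provides one. During every reannealing step of PCR on a
diverse pool, a strand almost never finds its exact complement; it forms a
probabilistically self-assembled *mismatched* heteroduplex instead. With
`m` mismatches a 60-bp duplex melts ~`m` degrees earlier, holds less
double-strand-binding dye at the elongation temperature, and fluoresces
less. The amplification curve therefore encodes two things at once:

* **template concentration** — the usual horizontal shift of the threshold
  cycle Ct, ~3.3 cycles per 10-fold dilution;
* **library diversity** — the curve *shape*: a single sequence gives the
  classic sigmoid, a 4^20-member pool gives a *peaked* curve whose
  fluorescence collapses after the primers are exhausted and reshuffled
  mismatched pairs take over the duplex population.

`poolpcr` implements the forward model of this readout and its inverse:

* exact combinatorics of degenerate library specs (IUPAC FASTA in/out),
  Poisson-binomial mismatch distributions, biased-primer subsetting,
  per-member copy numbers;
* minimum-Hamming-distance code-set design (with a quaternary Plotkin
  feasibility bound) for sublibrary barcodes;
* a cycle-by-cycle PCR simulator over mismatch-count histograms: competitive
  primer-vs-strand annealing, re-equilibration bias, extension with primer
  consumption, dye-weighted fluorescence, pool functional factor F, a
  finite-copy stochastic mode, and a network-extension mode for the
  high-molecular-weight "high-entropy" aggregates of late-cycle diverse
  pools;
* selection models: restriction-site protection by flanking mismatches, and
  streptavidin-bead capture/wash selection over tagged code libraries;
* the inverse "analytical function": feature extraction (Ct, endpoint, peak,
  decline ratio, shape class) and nearest-neighbor estimation of diversity
  and concentration against a simulated calibration bank.

## The model in brief

Per cycle (melt → anneal → extend), with sense/antisense strand
concentrations `S = T`, primer concentration `P`, and effective species
number `N`:

* a sense strand hybridizes with primer B′ with probability `P/(P+T)`,
  otherwise with a random antisense strand;
* a strand–strand pairing is perfectly matched with probability
  `min(1, 1/N + ε)`; otherwise its mismatch count `m` follows the library's
  Poisson-binomial pairwise law conditioned on distinct members
  (`m ~ Binomial(20, 3/4)` for `N20`);
* primer–template hybrids extend with efficiency 0.95 into perfect
  duplexes, consuming primer;
* fluorescence = Σ duplex classes × dye factor
  `σ(( Tm(m) − T_elong )/w) / σ(( Tm(0) − T_elong )/w)` with
  `Tm(m) = 82 − 1.2 m` °C and `w = 2.5` °C, normalized to a
  single-sequence reference plateau;
* the functional factor `F(m)` interpolates monotonically through
  `F(0) = 1.0`, `F(7.5) = 0.5`, `F(15) = 0.1` — the anchor abscissae are the
  mean pairwise mismatch counts of 10- and 20-position fully degenerate
  libraries; pool F is the concentration-weighted mean.

## Worked example

```python
import poolpcr as pp
from poolpcr.fixtures import s1, x_n
from poolpcr.curves import extract_features

for lib in [s1(), x_n(2), x_n(10), x_n(20)]:
    feats = extract_features(pp.simulate(lib, pp.SimConfig()))
    print(f"{lib.name:6s} Ct={feats.ct:5.2f} endpoint={feats.endpoint:.3f} "
          f"decline={feats.decline_ratio:.3f} {feats.shape_class}")
```

prints (45 cycles, 100 pM template, 50 nM primers, elongation 72 °C):

```
S_1    Ct= 5.97 endpoint=1.000 decline=0.000 sigmoidal
X_2    Ct= 5.97 endpoint=0.980 decline=0.000 sigmoidal
X_10   Ct= 6.00 endpoint=0.599 decline=0.131 intermediate
X_20   Ct= 6.02 endpoint=0.057 decline=0.882 peaked
```

All four pools amplify equally well (near-identical Ct), but the endpoint
falls and the curve becomes peak-shaped as diversity grows: a 16-member pool
is indistinguishable from a single sequence, while the 4^20 pool loses ~94%
of its peak fluorescence to mismatched reshuffling. The inverse estimator
reads these features back:

```python
from poolpcr.curves import build_bank, estimate
bank = build_bank(range(2, 21, 2), [1e-12, 1e-11, 1e-10, 1e-9])
est = estimate(feats, bank)          # feats from the X_20 run above
print(est.diversity, est.concentration)   # 1099511627776 1e-10
```

The same machinery is exposed on the command line:

```bash
poolpcr fixtures --out fixtures/
poolpcr design --n 10 --length 20 --min-dist 16 --seed 1 --out codes.fasta
poolpcr simulate --library fixtures/libraries.fasta --name X_20 --out traj.csv
poolpcr analyze traj.csv
poolpcr digest --pretreat-cycles 5 --out digest.csv
poolpcr select --tags fixtures/lib_d_tags.tsv --washes 2 --out outcome.csv
```

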