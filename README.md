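# ygeneflow

Simulation and statistics for Y-chromosome introgression across deep
species boundaries, built around the guenon (*Cercopithecus*) system in
which the *C. denti* Y chromosome clusters with the *mitis* species group
instead of with its autosomal sister species *C. wolfi*.

The package is for population geneticists who want to (a) bound how much
autosomal gene flow could have accompanied an introgressed Y, and (b) ask
whether drift alone can fix a foreign Y from a low starting frequency, or
whether selection is required — plus the supporting genome scans
(pseudoautosomal-region detection, copy-number candidates, window
topologies, coding-gene screens), all runnable on synthetic data with
planted ground truth.

## Core models

**Structured coalescent with pulses.** A demographic model is a species
tree with per-branch effective sizes Ne, split times, and instantaneous
introgression pulses (time, source, destination, proportion phi).
Backward in time, lineage pairs in a population coalesce at rate
1/(2Ne); at a pulse each destination lineage relocates to the source with
probability phi.  Mutations are infinite-sites.  The D-statistic
experiment scans phi for the *mitis* → *denti* pulse and asks when

D = (ABBA − BABA) / (ABBA + BABA),  Z = D / SE_jackknife  (20 blocks)

becomes significantly positive (Z > 3) for the quartet
(P1 = wolfi, P2 = denti, P3 = mitis, O = macaque).

**Wright–Fisher Y fixation with a diffusion oracle.** A novel Y allele at
initial frequency p0 among N/2 Y copies experiences haploid selection
p′ = p(1+s)/(1+ps) and binomial resampling; outcomes are fixed / lost /
segregating.  The independent check is Kimura's diffusion formula
u(p0) = (1 − e^(−2Nsp0)) / (1 − e^(−2Ns)), with u = p0 under neutrality.

**Scaling conventions.** Y-linked models use Ne/4 and doubled pulse
proportions (male-mediated dispersal).  Divergence converts to time as
t = (dXY / 2μ)·g with μ = 4.82e-9 /bp/generation and g = 10 years.

See `docs/methods.md` for the full model description, parameter defaults
and numerical choices.

## Worked example

Fixation probability of an introgressed Y at 0.4% initial frequency with
a selective advantage of s = 0.001 in a population of 200,000 (100,000 Y
copies), 100 replicates of 100,000 generations:

```
$ ygeneflow fixation --n 200000 --s 0.001 --p0 0.004 --gens 100000 --reps 100 --seed 7
{
  "fraction_fixed": 0.47,
  "fraction_lost": 0.53,
  "fraction_segregating": 0.0,
  ...
  "ci_fixed_low": 0.37510817959341275,
  "ci_fixed_high": 0.5671114302990065,
  "kimura_prediction": 0.5506710358827784
}
```

47 of 100 replicates fixed; the 95% CI (0.38–0.57) brackets the diffusion
prediction of 0.55.  Despite a starting frequency of only 0.4%, a
selection coefficient of one part in a thousand fixes the foreign Y about
half the time — whereas the neutral fixation probability would equal the
initial frequency, 0.4%.

Other entry points: `ygeneflow simulate` (genotypes under the fitted
demography), `ygeneflow dstat|fd|dxy` (site statistics from VCF),
`ygeneflow par-scan|cnv-scan` (coverage scans), `ygeneflow topo-scan`
(window NJ topologies), `ygeneflow coding-scan` (fixed amino-acid
differences), `ygeneflow synth ...` (synthetic bundles with truth files),
`ygeneflow fig6a|fig6b` (the two headline experiments), and
`ygeneflow report` (consolidated genome scans).

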