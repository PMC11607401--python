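# Methods

`ygeneflow` implements the simulation and statistical machinery needed to
test whether a Y chromosome introgressed across a deep primate species
boundary and whether its fixation required positive selection.  The system
it models is the guenon radiation (*Cercopithecus*): the *C. denti* Y
chromosome clusters with the *mitis* group rather than with its autosomal
sister species *C. wolfi*, and the package quantifies how much autosomal
gene flow could have accompanied that Y, and how probable Y fixation is
with and without selection.

## Demographic model

The demography is a nine-taxon species tree (denti, wolfi, pogonias, mona,
neglectus, cephus, nictitans, *C. mitis opisthostictus*, macaque outgroup)
with three unidirectional introgression pulses:

1. 2.1% from the mitis-group ancestor into the ancestor of
   (denti, wolfi, pogonias) at 310,000 generations ago;
2. 8.5% from the cephus branch into the same recipient at 270,000
   generations ago;
3. a configurable proportion (fitted value 0.2%) from
   *C. m. opisthostictus* into *C. denti* at 100,000 generations ago,
   10,000 generations after the denti/wolfi split at 110,000 generations.

Time is measured backward from the present in generations; years are a
reporting conversion (`t_years = t_gen * g`, default generation time
g = 10 years).  The mutation rate is 4.82e-9 substitutions/bp/generation.
Pulses are instantaneous single-generation events, not continuous
migration bands.

Only two internal node ages are pinned by the fitted history (the
denti/wolfi split at 110 kgen and the ~8 Mya mona/mitis crown); the other
split times are package defaults chosen to be consistent with the pulse
schedule (pogonias joins at 200 kgen, mona at 380 kgen, the mitis crown at
250 kgen, cephus+mitis at 650 kgen, neglectus at 900 kgen, macaque at
1,350 kgen).  Branch-specific effective sizes are not published
numerically; every branch defaults to Ne = 200,000 diploids (the forward-
simulation census size, consistent with "generally large, >100,000"), and
all of these values are overridable through the YAML config.

Y-linked mode divides every Ne by four (Ne_Y/Ne_auto = 0.25 under an even
sex ratio and equal variance in reproductive success) and doubles every
pulse proportion, capped at 1 (purely male-mediated dispersal doubles the
effective Y migration rate).  `harmonic_mean_ne` collapses multi-epoch
branches into the single Ne with the same total coalescent intensity.

## Coalescent simulation

The simulator is a structured coalescent: between event boundaries each
population with k lineages and size Ne coalesces pairs at rate
k(k-1)/(4 Ne) with exponential waiting times (exact event scheduling, no
generation loop); at a pulse each lineage in the destination moves to the
source with probability phi; at a split derived lineages move to the
ancestral population.  A diploid sample contributes two lineages in
autosomal mode and one in Y mode.  Mutations follow the infinite-sites
model, Poisson over branch length x mu x locus length.

Intra-locus recombination is deliberately not simulated: long recombining
sequence is represented by many independent non-recombining loci.  The
locus count is therefore the resolution knob.  For the migration-grid
D-statistic experiment the default is 100,000 independent 10-kb loci per
replicate, chosen to match the genealogical resolution of a 100 Mb
recombining genome: the expected number of tree-changing recombinations is
of order 4 Ne r L = 4 x 2e5 x 4.48e-9 x 1e8 ~ 3.6e5, discounted to 1e5
for the strong autocorrelation of neighbouring genealogies.  With far
fewer loci the D-statistic's block-jackknife error is dominated by
genealogical noise and the significance threshold moves to much higher
migration rates; the locus count changes the variance of D, not its
expectation.

The per-locus kernel is JIT-compiled (numba) and shared by the tree API,
the monophyly counter and the batched ABBA/BABA accumulator, which
exploits the infinite-sites property that every mutation on a branch
produces the same site pattern (one Poisson draw and one pattern weight
per branch instead of per-site genotypes).  Replicate seeds derive from
one user seed through a counter-based stream (`numpy.SeedSequence`), so
replicates are reproducible and order-independent.  The TMRCA distribution
of the simulator is cross-checked against msprime in the test suite.

## Wright-Fisher forward model and diffusion oracle

The fixation experiment tracks a novel Y haplotype as a frequency among
N/2 Y copies in a census of N diploids: per generation, deterministic
haploid selection p' = p(1+s)/(1+ps) followed by binomial resampling.
This frequency-based model has the same diffusion limit as an
individual-based Y simulation and runs the full 200,000-individual,
100,000-generation grid in seconds (replicates vectorised, one binomial
draw per generation for all unabsorbed replicates).  Outcomes are
reported as fixed / lost / still-segregating; segregating is never folded
into the absorbed classes.  The initial copy number rounds to the nearest
integer with a floor of one copy (an introgressed Y exists as at least one
male).

The independent oracle is Kimura's diffusion fixation probability for a
haploid population, u(p0) = (1 - e^(-2Nsp0)) / (1 - e^(-2Ns)) with N the
Y-copy number, u = p0 at s = 0, evaluated overflow-safely.  At
(s = 0.001, p0 = 0.4%, N = 1e5) the diffusion value is 0.551; at
p0 = 0.8% it is 0.798.  Simulated fractions agree with the oracle within
three binomial standard errors across the (s, p0) grid.

A note on horizons: under selection 2Ns = 200 the conditional sweep time
(~(2/s) ln 2Ns ~ 2e4 generations) fits comfortably inside the 100,000-
generation experiment, so truncation does not bias the selected cells.
Under neutrality the conditional fixation time is ~2N = 200,000
generations, so the neutral identity u = p0 is checked on runs taken to
absorption; the 100,000-generation horizon is retained for the grid
experiment, where "still segregating" is itself a reported outcome.

The two-locus Y-PAR model gives each Y chromosome a pseudoautosomal
allele; each male meiosis swaps it with a random allele from the X-borne
pool (three X copies per Y copy) with the per-generation recombination
probability, and each compartment then drifts binomially.  The
association between donor-Y background and donor-PAR allele decays as
(1 - r)^t, which the tests verify against the fitted log-slope; the
PAR profile utility maps bins at increasing distance from the Y boundary
to increasing r (multiplier x 4.48e-9/bp x distance).

## Site statistics

Genotype filters reproduce standard masking rules: heterozygous calls
with minor-allele read fraction < 0.25 become missing; per-sample calls
outside [0.5x, 2x] of the relevant mean depth become missing (boundaries
retained inclusively); Y-chromosome sites heterozygous in any sample are
dropped for all samples.

ABBA/BABA counting is frequency-weighted (Dsuite-style): per biallelic
site polarized by the outgroup, ABBA += (1-p1) p2 p3 and
BABA += p1 (1-p2) p3; sites with a polymorphic or missing outgroup are
skipped, and sites where the outgroup is fixed derived are flipped before
weighting.  D = (ABBA-BABA)/(ABBA+BABA).  Significance uses the
delete-one block jackknife over 20 equal-length genomic spans per
chromosome, SE = sqrt((n-1)/n * sum (D_-i - mean)^2), with Z > 3 as the
one-sided significance rule.  Windowed f_d follows the Martin et al.
dynamic-donor definition (P_D is per site whichever of P2/P3 has the
higher derived frequency; windows with non-positive numerator report 0).

dXY uses the honest denominator: summed cross-population allele-pair
differences over summed comparisons at all comparable sites, invariant
sites included, so missing data shrink the denominator and never inflate
divergence.  Windows default to 50 kb with a minimum of 100 comparable
sites (the source method is silent here; the floor suppresses
noise-dominated windows).  Divergence scales to coalescence time as
t = (dXY / (2 mu)) * g.

## Coverage scans

PAR detection: a male's X coverage in 10-kb windows, normalized by the
autosomal mean, is ~1.0 in the recombining PAR and ~0.5 elsewhere.  The
track is thresholded at 0.75 and smoothed by absorbing runs shorter than
the minimum run length, cheapest first, where a run's cost is its summed
squared distance to the opposite plateau minus that to its own — so a
borderline noise spike flips before a well-supported short run.  The PAR
is the terminal ~1.0 segment anchored at a chromosome end (both ends
searched); a female track, when given, must be ~1.0 across the call.  The
default minimum run is 10 windows: with Poisson noise at ~20x depth a
window lands on the wrong side of 0.75 with probability ~0.1, so 5-window
runs flip by chance at rates that misplace the boundary; ten consecutive
contrary windows are required before the segmentation accepts a state
change, which keeps the boundary error within two windows across noisy
replicates.  Both parameters are configurable.

CNV scan: 5-kb windows normalized per chromosome, target/reference ratio
per window, calling runs of at least `min_span_windows` windows at ratio
>= 2.0, merging across gaps of up to two sub-threshold windows (depth
noise dips single windows), and requiring the call to pass against every
reference when several are given.

## Window topologies and coding screen

Per 10-kb window a p-distance (optionally Jukes-Cantor corrected) matrix
feeds canonical Saitou-Nei neighbor joining with a deterministic
tie-break (lowest index pair) and negative branch lengths clamped to zero
with the deficit moved to the sister branch.  NJ is exact on additive
matrices (property-tested) and cross-checked against scikit-bio.  After
rooting on the outgroup, a window is classified `y_like` only if the
focal taxon is nested inside a monophyletic donor-group clade, sister to
the donor species, with its own group (without it) still monophyletic;
`species_like` requires the focal taxon sister to its species-tree sister
inside its own monophyletic group.  Windows with more than 50% missing
data or fewer than 20 variable sites are `unresolved` (both
configurable); adjacent `y_like` windows merge into regions.

The coding screen translates single-CDS-per-gene alignments with the
standard code (ambiguity -> X), excludes genes with an internal stop in
any focal sample, and counts positions where each clade is fixed for a
different residue; a single non-missing call per clade suffices at a
position (the source is silent on per-site missingness).

## Synthetic data

The generator produces every input the pipeline consumes, each with a
machine-readable truth file: genotype VCFs (with explicit invariant-site
records so dXY denominators are honest) under the fitted demography at a
chosen pulse-3 phi; male/female coverage tracks with a planted 2.36-Mb
PAR plateau and planted fold-change CNV regions under Poisson depth noise
(negative-binomial overdispersion is not modelled — the plateaus differ
by >= 2x so the noise family is not critical); and CDS fixtures with
planted fixed differences and stop-codon injections.  What the synthetic
data does not emulate: mapping bias, repeat-driven missingness,
linked selection, or recombination within loci — so passing tests
demonstrate correctness of the machinery on its stated model, not
performance on accession-scale sequencing data.

## Problem sizes

The shipped experiments run on one CPU: the fixation grid (16 cells x 100
replicates x 100,000 generations) in under a minute; the neutral
absorption check (10,000 replicates to absorption) in ~30 s; the full
migration grid (21 rates x 10 replicates x 100,000 loci) in ~2-3 minutes.
The test suite uses smaller configurations of the same machinery.

## Known limitations

- Independent loci approximate recombining sequence; the D-statistic's
  variance (hence the detection threshold's exact position) depends on
  the locus-count choice documented above.
- The Wright-Fisher Y model assumes Poisson-equivalent offspring variance;
  an individual-based simulator with SLiM-like mating can realise slightly
  different effective sizes.
- Selection against hybrid backgrounds (Haldane-rule incompatibilities)
  is not modelled; estimates of s needed for fixation are conservative.
- The PAR/CNV scans are plateau detectors, not breakpoint genotypers.
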