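# Methods

This note documents the models, conventions, and numerical choices
behind `anaspop`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates, genotypes, and I/O conventions

VCF I/O is 1-based; all window logic is 0-based half-open, converted in
one place (`pos - 1`). Genotypes are coded 0/1/2 alternate-allele
dosages with −1 for missing; half-calls (`0/.`) are treated as fully
missing — the simplest defensible convention, applied uniformly.
Multiallelic records are split into one biallelic record per ALT, with
alleles belonging to a non-focal ALT recoded as reference (all
downstream statistics are defined for biallelic sites; how the original
pipeline handled these is not documented, so the choice is ours and is
isolated in `read_vcf`). Annotation floats are stored at float32
precision, the VCF on-disk precision, so write→read round-trips are
exact.

## Variant QC

The hard-filter thresholds are applied as strict inequalities. Records
lacking an annotation pass that criterion by default (with a warning),
because synthetic fixtures and third-party VCFs do not always carry the
full GATK annotation set; a switch inverts this.

Two rules in this stage are ambiguous in their usual verbal statement,
and we pin interpretations:

* **SNP clusters.** "More than 3 SNPs in a 10-bp window" is implemented
  as a sliding rule: a SNP is removed iff it belongs to 4
  position-consecutive SNPs spanning ≤ 10 bp (equivalently, some 10-bp
  interval containing it holds ≥ 4 SNPs). All SNPs of an offending run
  are removed. The alternative disjoint-window reading is not provided;
  the sliding rule is the stricter and the order-independent one.
* **Allele depth.** "Alternate depth less than half the site depth" is
  aggregated over carrier samples (het or hom-alt), boundary inclusive
  (exactly half is kept); a per-sample variant of the rule is available
  via `per_sample=True`. Note that at ~6× coverage this rule is
  intentionally aggressive: a heterozygous singleton has binomial
  alternate depth and falls below half roughly 40% of the time, which
  is visible in the worked example's filter report.

The structure-site filter keeps SNPs with minor allele frequency
strictly above 0.1 and genotype call rate strictly above 0.9.

## Windowed diversity and differentiation

Windows are 10 kb with a 5-kb step (defaults), wholly contained in
their scaffold, on scaffolds strictly longer than 10 kb. Per-site π is
2j(n−j)/(n(n−1)) with n the called haplotypes at the site (no
imputation); per-bp window π divides by the full window length, the
VCFtools `--window-pi` convention, so monomorphic and uncalled bases
count as zero diversity. Window F_ST is the Weir–Cockerham (1984)
estimator as a ratio of summed variance components Σa / Σ(a+b+c) —
not a mean of per-site ratios — with negative θ̂ retained so the
empirical Z distribution matches the estimator's support. Windows with
no informative site have undefined F_ST and are excluded from
quantiles and Z-standardization. Z(F_ST) standardizes by the empirical
mean and SD (ddof 1) of the defined window values.

The joint outlier rule selects windows at or above the top-q
nearest-rank thresholds of both Z(F_ST) and log₂(π_wild/π_dom),
ties inclusive. Windows where domestic diversity is exactly zero but
wild diversity is positive have an unbounded ratio: they are excluded
from the empirical ratio distribution (and reported as NaN with a
`ratio_unbounded` flag) but treated as exceeding any finite ratio
threshold during selection. At the scale of the synthetic genomes a
strong sweep regularly drives a 10-kb domestic window to zero
polymorphism, and these windows are precisely the extreme tail the
scan is designed to find; on deep real data the case is essentially
unreachable. Gene annotation uses ≥ 1 bp overlap on half-open
intervals, in both merged-region and raw-window modes.

## Folded joint SFS

Sites project down to m haplotypes per population with hypergeometric
weights C(j,i)C(n−j,m−i)/C(n,m); sites with fewer called haplotypes
than the projection are skipped and counted. Projection sizes are
chosen by maximizing the expected number of segregating SNPs over even
haplotype counts from 4 to the full sample size (diploid samples), with
the segregating mass computed in closed form from the per-site
monomorphism probabilities. Folding is on the pooled minor allele;
cells at exactly 50% pooled frequency keep half-mass in each mirrored
cell (the convention of the diffusion-method ecosystem, pinned by a
hand-computed fixture). Thinning to alleviate linkage is seeded uniform
sampling without replacement at an exact count (a systematic every-kth
mode is available). Noncoding-region restriction is a BED-mask
intersection, not annotation parsing.

## Structured-coalescent simulator

The generator is an exact backwards-in-time structured coalescent:
within-deme pairwise coalescence at rate C(k,2)/ν, per-lineage
migration hops at the scaled rates M = 2N_ref·m, lineage pooling at
split times, piecewise-constant sizes. Times are in units of 2N_ref
generations, θ = 4N_ref·μ per site, and a branch of scaled length ℓ
spanning L bp receives Poisson(ℓ·θ/2·L) infinite-sites mutations at
distinct uniform positions. Branch-mode accumulation (expected branch
length per descendant-count cell) gives low-variance expected SFS; the
same loop yields full genealogies for cohort simulation. Correctness is
checked against closed forms (E[T₂], E[π], E[S], ξ_i ∝ 1/i, d_xy) and
against msprime on island models (TMRCA means and branch-SFS
total-variation distance).

The cohort defaults are the emulated study conditions: nine populations
(MDN 8, MDZ 14 wild; PK/CV/ML 8 meat; JD/SM/SX 8 egg; GY 8
dual-purpose; 78 diploids) mapped onto three demes, the
single-domestication demography at its published maximum-likelihood
values, μ = 1.191 × 10⁻⁹, mean sequencing depth 6.42×, 5% missing
genotypes, and an INDEL fraction of 7.9% with geometric lengths tuned
so 1-bp INDELs predominate and deletions slightly outnumber insertions.
The reference size N_ref = 100,000 (the pre-size-change ancestral
population) is not published and was fixed once as a realistic mallard
value; all recovery experiments compare a profiled parameter against
the value that was simulated, so this choice sets the stage rather
than the answer.

Key simplifications relative to real data: genealogies are independent
between 10-kb segments and fully linked within them (no recombination,
no LD decay within windows); QC annotations are synthesized from
passing ranges (with a switch to inject failures) rather than derived
from reads; sweeps are emulated by dividing the domestic demes'
coalescent sizes (including the short-lived common domestic ancestor)
by a factor f inside designated windows, which reproduces the
π-reduction/F_ST-elevation signature with one interpretable parameter
but no hitchhiking haplotype structure; diagnostic loci are inserted
as exactly fixed differences. Passing tests therefore demonstrate the
statistics and the inference machinery, not robustness to
recombination, mapping artifacts, or soft sweeps.

## Demographic models and fitting

Four scenarios share three sampled demes (wild, meat, egg/dual-purpose)
plus ancestors: simultaneous domestication (trifurcation, k=8 free
parameters), single domestication with a bottlenecked common domestic
ancestor then breed divergence (k=10), and two independent
domestications with meat or egg first (k=9 each). All include an
ancient ancestral size change and continuous migration into the wild
deme from each breed after its divergence; the 102-year window between
domestication and breed divergence in the single-domestication model
carries no migration (unspecified in the source analyses, and too short
to matter). Population sizes are piecewise-constant; breed expansion is
an instantaneous size change at the breed-divergence event rather than
exponential growth, matching the model type's contract and keeping
every deme single-sized (which the importance reweighting below
exploits).

Expected spectra are Monte-Carlo branch-mode SFS, normalized over
unmasked cells with a 10⁻¹⁰ pseudocount in empty cells. The objective
is the Poisson composite log-likelihood with the overall θ̂ scale
profiled analytically (model = expected proportions × Σobs). Fits use
Nelder–Mead on log-parameters with common random numbers (a fixed
Monte-Carlo seed per fit makes the objective deterministic), multiple
independent restarts (10 by default), and a convergence flag when the
two best restarts agree; non-convergence is reported, never raised.
Parameter uncertainty is a percentile bootstrap: scaffolds resampled
with replacement, spectrum rebuilt, parameters refit.

One-parameter profile likelihoods (the parameter-recovery experiments)
use two evaluation strategies:

* **Split times** change the event structure, so each grid value is
  evaluated with a fresh simulation at a shared seed; a coarse log grid
  over [0.5×, 2×] truth (clipped to the scenario's event ordering) is
  followed by a zoomed grid in the best bracket and a log-space
  parabola vertex.
* **Sizes and migration rates** scale event intensities, so one set of
  genealogies simulated at the base parameters is reweighted exactly to
  every grid value via the path likelihood ratio
  (rate'/rate)^{events} · exp(−(Λ'−Λ)), computed from tracked
  integrated coalescent intensities, hop counts, and channel
  lineage-time integrals. Because every grid point reuses the same
  genealogies, the profile is smooth in the parameter and its argmax is
  far more precise than independent re-simulation at the same cost.
  Effective sample sizes are monitored and a warning is emitted when
  reweighting is stretched thin at the grid edges (the refinement pass
  re-centres near the optimum where weights are ≈ 1).

Problem sizes were chosen to resolve each parameter well inside its
reported uncertainty on a single CPU: 100,000 SNPs at 16 haplotypes
per population for the observed spectrum, 60,000 genealogies for the
data-generating spectrum, 40,000 reweighted genealogies per
importance-sampling pass, and 6,000 per point-wise evaluation.

Scenario comparison at scale (20 replicates of 10⁵ SNPs) uses a
grid-profile maximum likelihood: a seeded candidate-parameter set per
scenario — each scenario's best mimic of the single-domestication
truth, local jitters of it, and broad log-uniform draws — whose
expected spectra are computed once and reused across replicates. AIC
uses each scenario's free-parameter count. This deterministic protocol
replaces per-replicate simplex refits, which a single CPU cannot
afford; it slightly favors no scenario, since all four receive the
same candidate budget and analogous mimic points.

## Real-unit scaling

N_ref = θ̂/(4μL); sizes are ν·N_ref individuals, times T·2N_ref·g
years (g = 1 year), and migration M·ν_recipient/2 migrants per
generation into the recipient — the conversion round-trips exactly and
is pinned by tests (e.g. 3.92 migrants/generation into a wild deme of
ν = 0.88842 corresponds to M = 8.8247).

## Known limitations

* No recombination within windows; linked-selection signatures and
  LD-based statistics are out of reach of the generator.
* The composite likelihood treats SNPs as independent; with thinned
  data this is the standard approximation, but the reported likelihood
  units are not comparable across datasets with different linkage.
* Importance-sampling profiles require the profiled deme to keep one
  size for its whole lifetime (true of all provided scenarios) and a
  strictly positive base migration rate for migration parameters.
* The NJ implementation targets exactness on additive matrices and
  deterministic tie-breaking, not large-matrix performance.
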