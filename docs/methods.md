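# Methods

## Model overview

matesim is a gene-dropping (forward-in-time) simulator of a closed breeding
population with discrete generations, followed by SNP-BLUP genomic
prediction.  The pipeline has four stages — historical population,
expansion, recent (design) phase, prediction/metrics — each of which is an
importable function; the scenario layer (`experiment.py`) only wires them
together and manages seeds.

### Genome and trait

One chromosome of 100 cM carries equally spaced bi-allelic markers
(`i·L/m`, i = 1..m) and QTL at uniform random positions.  QTL are placed
*between* markers, never on them: the predictor observes markers only, so
all predictive signal must travel through marker–QTL LD, which is the point
of the study design.  QTL effect magnitudes are gamma(shape 0.4, scale 1);
the scale is irrelevant because effects are rescaled later.  Signs are ±1
with probability ½ each — gamma draws are positive, and a trait whose every
allele pushed one direction would be pathological.

The effect vector is multiplied by one constant so that the population
variance of TBV = Σ dosage·effect equals h²·σp² in the **recent founder
cohort** (the 50 + 3,500 animals that start the design phase).  Phenotypes
add N(0, (1−h²)σp²) noise.  Scaling at the recent founders rather than the
historical base means heritability holds exactly where phenotypes are
actually recorded; genetic variance then drifts freely under the design.

### Historical phase

Founders start with allele frequency ½ at every locus (the long
drift–mutation phase, not the initialization, shapes the final spectrum —
the initialization is a convention, flagged as such).  Census size follows
linear interpolation between anchors (1,000 → 10,000 at generation 1,000 →
4,000 at generation 2,020), rounded to even so both sexes always exist.
Each offspring takes a random sire and random dam with replacement
("gametic pool" mating).  Meiosis is Haldane: crossover count ~
Poisson(map length in Morgans), positions uniform, no interference; each
transmitted allele then mutates (0↔1 flip) at 2.5×10⁻⁵ per locus per
generation.  The final historical generation is produced with exactly the
sex split the expansion phase needs (e.g. 500 M + 3,500 F = 4,000): an even
split of 4,000 could not supply 3,500 dams, so this is read as the
simulation convention of specifying the last generation's sex numbers.

### Expansion phase

Sires and dams drawn at random (without replacement) from the last
historical generation; every dam gets a random sire and 5 offspring per
generation for 10 generations; offspring sex is Bernoulli(½).  The dam
quota grows by factor litter/2 per generation — exponential dam growth — but
is capped at `dam_growth_cap` (default 2×) times the initial count.  An
uncapped ×2.5 growth over ten generations would end at ~33 million animals,
which no one can have simulated; since only 50 sires + 3,500 dams are
sampled out of the expanded population afterwards, expansion depth beyond a
few-fold mainly lowers founder relatedness and adds little after that.  The
sire quota keeps the initial sire:dam ratio.

### Recent phase and mating designs

The recent founders start a new pedigree (F = 0 base, as pedigree methods
assume).  Kinship among the current parents is tracked exactly by the
recursion K(o₁,o₂) = ¼ΣK(parents), K(o,o) = (1 + K(s,d))/2, which equals
the tabular method on the full pedigree (verified in the tests) but only
ever stores a parents × parents matrix.

Every design produces a mate plan in which each dam appears once and sire
usage is balanced to ±1 dam (70 dams/sire at full scale), so designs
differ only in *pairing*:

* assortative designs rank candidates on EBVs.  The default EBV is the
  regressed phenotype deviation h²(y − ȳ): the study leaves the estimator
  implicit, every candidate has a record, and for ranking purposes any
  monotone shrinkage of the phenotype is equivalent.  A dense animal-model
  pedigree BLUP (`estimate_ebv(method="pedigree_blup")`) is available for
  sensitivity runs on small pedigrees.
* min/max inbreeding run simulated annealing on the mean parental kinship
  of the plan.  T₀ = 0.5 cooled by ×0.9 per sweep; one proposal per dam per
  sweep; the move swaps the sires of two random dams (preserves balance);
  Metropolis acceptance uses the *summed* objective, whose natural scale
  (~10⁻¹–10⁰) matches the stated temperature schedule, whereas a mean-scale
  Δ (~10⁻⁴) would leave the whole schedule effectively hot.  Stopping: T <
  10⁻⁴ (≈81 sweeps) or 50 sweeps without improving the best-so-far plan,
  which is what is returned.  On 3×3 instances the optimizer matches
  exhaustive enumeration on 100/100 restarts.

Next-generation parents (50 sires, 3,500 dams) are drawn **at random**
among offspring: the study specifies the mating design but no selection
rule, and random replacement ensures observed differences are attributable
to the design rather than to selection response.  Litter size stays 5.
Generations 3–9 form the reference set, generation 10 the validation set.

### Prediction and metrics

RR-BLUP solves the (m+1)-dense mixed-model equations exactly (Cholesky;
positive definite for λ > 0).  Markers fixed in the reference set are
dropped (zero-variance columns carry no signal).  λ comes from the true
variance components: σg² = h²σp²/Σ2pⱼqⱼ with pⱼ the reference-set allele
frequencies, λ = (1−h²)σp²/σg² — the simulator knows h², so no REML step is
needed; a user-supplied λ is accepted.  GEBV = Xĝ without intercept.
Accuracy is the Pearson correlation of TBV and GEBV; bias is the OLS slope
of TBV on GEBV over reference + validation animals pooled.  LD r² uses true
phase (the simulator knows it), excludes monomorphic markers, and is binned
(lo, hi] up to 5 cM in the standard decay-table layout.  Replicate
summaries report mean ± sd/√R.

## Scale presets

Runtime scales with census × generations, so the package ships proportional
miniatures of the full-scale structure.  Historical census sizes *and*
historical generation counts are shrunk by a common factor: drift and LD
equilibrate on a timescale of ~N generations, so shrinking both preserves
the shape of the equilibrium and bottleneck in miniature (absolute r²
levels rise as 1/Ne — the desk-scale mean r² of ~0.04 vs the full-scale
~0.017 is expected, not a bug).

| preset | historical anchors | expansion | recent | intended use |
|---|---|---|---|---|
| full | 1000 → 10000 (g1000) → 4000 (g2020) | 500♂ × 3500♀ | 50♂ × 3500♀ | complete-structure runs |
| desk  | 100 → 1000 (g100) → 400 (g202)      | 50♂ × 350♀   | 50♂ × 350♀  | default analyses, acceptance |
| micro | 50 → 500 (g50) → 160 (g101)         | 20♂ × 140♀   | 20♂ × 140♀  | fast smoke/grid checks |
| mini  | 25 → 250 (g25) → 80 (g50)           | 10♂ × 70♀    | 10♂ × 70♀   | directional/property tests |

`desk` deliberately keeps the full-scale 50 recent-phase sires while shrinking
dams tenfold: recent-phase effective size is dominated by the rare sex
(Ne ≈ 4·Ns·Nd/(Ns+Nd)), and that Ne is the quantity the mating designs act
on.  With 12,250 reference animals against at most 950 markers the desk
preset keeps n ≫ m, so prediction accuracies land close to the full-scale
values; the analysis scripts and acceptance checks therefore use desk sizes
(reference n = 12,250, validation n = 1,750, 3–5 replicates), with mini
sizes for purely directional contrasts.

## Sharing historical populations across scenarios

Grids optionally simulate one dense base (950 markers + 200 QTL) per
replicate and thin it per scenario: markers nearest to the sparser grid,
QTL a random subset.  Marginalising a neutral simulation over a locus
subset is exact — loci influence nothing but themselves — so thinned runs
are distributed identically to dedicated runs (checked empirically in the
tests), and marker-density comparisons share genetic background.

## Numerical choices and degenerate inputs

* RNG: numpy PCG64 generators; every stage gets a child of
  `SeedSequence([master_seed, replicate, ...])`, so runs are bit-reproducible
  and replicates/scenarios are independent streams.
* If every QTL is fixed in the scaling cohort the trait is degenerate; the
  replicate resamples QTL effects/positions (up to 5 attempts) rather than
  silently producing a flat trait.
* Accuracy/bias raise on zero-variance inputs instead of returning NaN.
* Assortative ranking breaks EBV ties by animal id, making plans
  deterministic given EBVs.
* Mutation flips are applied via XOR at Poisson-thinned random indices; a
  duplicate index (probability ~(μnL)²/2nL) cancels two flips, a negligible
  and unbiased approximation.

## What the generator does and does not emulate

The simulator reproduces the *structure* of the study: neutral historical
LD, the bottleneck, the two-tier breeding pyramid, balanced sire usage, and
trait architecture.  It does not model overlapping generations, selection,
culling, litter-size variation, dominance/epistasis, multiple chromosomes,
or genotyping error.  Passing tests therefore show that the method ranks
mating designs correctly and reproduces accuracy/bias/LD magnitudes under
these idealized conditions — not that the same magnitudes would be observed
in a real breeding scheme.

## Known limitations

* Full-scale runs (the `full` preset) are supported but slow (~hours per
  scenario grid); all shipped analyses use the smaller presets above.
* The Bayesian whole-genome regression alternative mentioned alongside
  RR-BLUP in the source study is out of scope; reported results do not
  separate the two estimators, and RR-BLUP is the implemented one.
* Mate-allocation optimizes *pedigree* kinship (as breeding simulators
  conventionally do), not genomic identity.
* At strongly reduced scale the absolute LD level is inflated (smaller Ne);
  orderings and decay shape are preserved, absolute r² is not.
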