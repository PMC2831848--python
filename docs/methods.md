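# Methods

## The statistic

`hacsweep` tests individual SNPs of a phased haplotype sample for the
signature of an *ongoing* (incomplete) selective sweep. The substrate is the
**haplotype allelic class (HAC)**: the Hamming distance between a haplotype
and a reference haplotype over a window of S biallelic SNPs. The reference
used throughout is the **major-allele reference haplotype (MARH)** — the
artificial haplotype carrying the majority allele at every SNP of the
window. Against the MARH, a haplotype's HAC is simply the number of minor
alleles it carries.

At an evaluated SNP k, the n haplotypes split into R_k — the carriers of the
allele present on the MARH at k (the major allele, except at exact 50/50
ties) — and r_k, the rest. With V̂ the unbiased sample variance of the HAC
values (denominator n−1; a `ddof` switch selects denominator n),

```
vd_k  = V̂(r_k) − V̂(R_k)
Svd_k = f_dk · vd_k / S
```

where f_dk is the derived-allele frequency at k within the analysed sample.
A sweep that has dragged a derived allele to high frequency leaves its
carriers (R_k, since the selected allele is then the major one) clustered
tightly around the MARH — V̂(R_k) small — while the remaining haplotypes
stay dispersed, so Svd is large and positive. Under neutrality vd_k centres
near zero or below (the larger class is, if anything, the more diverse
one). The f_dk weight focuses the test on *derived* alleles at high
frequency; high-frequency ancestral alleles are uninteresting for this
question and get small weight.

Conventions that the displayed quantities depend on:

* **Variance estimator.** Unbiased sample variance by default. Both n and
  n−1 denominators are consistent and asymptotically normal; the choice is
  exposed, not hidden.
* **Sign.** vd_k = V̂(r_k) − V̂(R_k), so that sweeps push vd_k positive.
* **Evaluated site.** SNP k's own column is part of the S-SNP haplotype and
  contributes to the HAC distances (every r_k haplotype starts one step
  from the MARH). `include_evaluated=False` excludes it for sensitivity
  analysis, which is also the reading used by some per-SNP candidate-locus
  analyses ("the haplotype consisting of the S−1 remaining SNPs").
* **Ties.** At derived frequency exactly 0.5 the MARH carries the ancestral
  allele — a deterministic rule, recorded per site, chosen because the f_d
  weighting already directs the statistic towards derived-major sites.
* **Undefined values.** If either allele class holds fewer than two
  haplotypes the variance contrast does not exist; the site is reported as
  missing (`defined=False`), never as zero, and such sites are excluded
  from calibration, power and scan percentiles. Zero-filling would drag
  every null quantile towards zero and mis-calibrate the test.

### Normalisation by S — what it does and does not achieve

HAC variances grow with window size, so vd_k is divided by S to make values
comparable across window lengths. The growth is *at most linear only in the
limit of free recombination*. Empirically, under the no-recombination
standard scenario the mean full-sample HAC variance grows almost
quadratically in S (log–log slope ≈ 1.9 over S = 26…201), because a single
shared genealogy correlates minor-allele indicators at arbitrary distance;
with ρ = Θ/2…Θ the slope drops to ≈ 1.3–1.4. Dividing by S therefore
removes most, not all, of the window-size dependence: Svd values from
different S remain on similar scales but are not strictly comparable, and
every calibrated quantity in this package is computed at fixed S for that
reason.

## Simulation harness

### Neutral scenarios

Neutral replicates come from msprime (standard coalescent, infinite-sites
binary mutations on a continuous genome, haploid samples with population
size 2·Ne so that pairwise coalescence happens at the diploid rate
1/(2Ne)). The validation scenarios are samples of n = 50 haplotypes at
Θ = 223 — about 1,000 SNPs per replicate, matching Watterson's
E[S] = Θ·Σ 1/i ≈ 999 — with optional uniform recombination at ρ = Θ/2,
recombination hotspots, a bottleneck (95% size reduction 340–260
generations ago) or an expansion (Ne 500 → 1,000 over the last 300
generations).

### Sweep scenarios

Sweep replicates use an in-package structured-coalescent engine (no
installed library exposes frequency-conditioned sweep genealogies together
with the identity of the selected-allele carriers):

1. **Trajectory.** The selected allele's frequency path is simulated
   backwards from its current value f to its origin at 1/(2N). The time
   reversal of a path since its origin is the forward Wright–Fisher
   diffusion *conditioned on loss*: Euler steps with drift
   −s·x(1−x)·coth(2Ns·(1−x)) and variance x(1−x)/(2N) per generation.
   Two limits pin this form down: in the interior (2Ns(1−x) ≫ 1) it is the
   logistic decline −s·x(1−x), and as s → 0 it reduces to −x/(2N), the
   Maruyama–Kimura allele-age process of a neutral allele — the
   *frequency-conditioned neutral* model used as the matched null. A
   deterministic logistic trajectory is available as a config switch; the
   stochastic variant is the default.
2. **Structured coalescent.** Each of the n sampled lineages (the number of
   selected-allele carriers is a Binomial(n, f) draw, conditioned on both
   classes having ≥ 2 copies) lives in the derived or ancestral background.
   Within-background pairs coalesce at rates 1/(2N·x) and 1/(2N·(1−x));
   recombination splits a lineage at a map-uniform breakpoint within the
   span of its ancestral material, and the piece on the far side of the
   selected site re-samples its background from x(t). At the origin the
   remaining derived lineages merge into the founding chromosome, and the
   process continues as a plain coalescent-with-recombination until every
   chromosome interval reaches its MRCA.
3. **Mutations.** Each lineage tracks, per interval, the set of present-day
   samples inheriting it; neutral mutations fall on ancestral material at
   rate Θ/(4N) per generation during the walk — exactly equivalent to
   Poisson mutations on every marginal-tree branch — so the carrier set of
   each mutation is known without tree extraction, and intervals that
   reach their MRCA stop accumulating (non-segregating) mutations.

In pure-neutral mode this engine reproduces msprime's summaries at the same
parameters (mean segregating sites 999 vs 992, mean π 220 vs 219, mean
distinct haplotypes per 51-SNP window 22.2 vs 22.0, mean r² at ~10 kb 0.067
vs 0.063; 60 replicates each) — the cross-check that the recombination
machinery is sound.

Parameter choices that the literature leaves open here:

* **Ne defaults to 1,000** (the "small" and "large" scenarios use 500 and
  2,000), with time in generations and Θ, ρ held at their population-scaled
  values across Ne variants, so Ne enters only through sweep dynamics.
* **Selection parameterisation**: genic, per-copy advantage s (forward
  drift s·x(1−x)). With fitnesses defined instead as 1, 1+s/2, 1+s the
  sweep takes twice as long; both parameterisations reproduce the published
  power table within its tolerance, and the per-copy reading is the
  default.
* **Locus** = 50 kb with SNPs on a continuous coordinate; hotspots are 2 kb
  wide (a typical human hotspot width), placed 2 kb downstream of the
  evaluated site, at 10× or 100× the background per-bp rate.
* **Windowing**: each replicate keeps its full SNP set; the S SNPs centred
  on the evaluated site are cut at analysis time, and replicates whose
  flanks cannot host the window are re-simulated with a fresh seed (counted
  in `ReplicateSet.n_regenerated`).

## Calibration and power

The critical value c at nominal level p is the smallest observed null value
with Pr(Svd ≥ c | null) ≤ p; detection power is the proportion of sweep
replicates with Svd *strictly* greater than c (the two definitions are
deliberately asymmetric, following their standard statements). The null is
**matched**: identical demography, recombination map, ascertainment and
windowing, with only the selection coefficient set to zero — which for a
sweep scenario means the *frequency-conditioned* neutral model, keeping the
evaluated allele at frequency f. This matters: conditioning is what gives
the null its realistic heavy upper tail (c ≈ 0.4–0.5 at p = 0.05 for the
default scenario). Calibrating against an unconditioned neutral central SNP
instead would shrink c by two orders of magnitude and inflate apparent
power to ≈ 1. The matched-null rule is enforced structurally:
`assert_matched_null` rejects any null/alternative config pair that differs
in more than s (and seed).

The critical value's Monte Carlo noise is worth respecting: it is a 95th
percentile of a heavy-tailed distribution, and at 200–300 null replicates
it wanders enough to move power estimates by ±0.05. The validation suite
uses 1,000+1,000 replicates for the ρ = 0 scenarios and 500+500 for the
recombination scenarios, whose per-replicate cost is 10–30× higher (the
strong-hotspot map multiplies the ancestral-recombination-graph event count
roughly fivefold).

Power–FDR curves sweep the decision threshold over the pooled null and
alternative values, with FDR = null exceedances / total exceedances (equal
prior weight per pool) and the reported operating point the largest
achievable FDR not exceeding the requested one.

## Ascertainment emulation

Three schemes thin the SNP set of a replicate before windowing, never
touching allele codes at retained sites: a minor-allele-count filter
(count < 3 at n = 50 removes MAF < 0.05, i.e. singletons and doubletons), a
discovery panel (keep sites segregating within m randomly drawn
chromosomes; a singleton survives with probability m/n), and Voight-style
spectrum-matching rejection sampling (acceptance ∝ target/source density
ratio over 25 equal-width derived-frequency bins, rescaled to maximum 1).
The evaluated site itself is never removed — it is the hypothesis under
test; removing it would silently change which site a power estimate refers
to. `diploidize` pairs haplotypes randomly into unphased genotypes (dosage
0/1/2, pairing recorded for exact round-trips) for hand-off to external
phasing tools; statistical phasing itself is out of scope.

## Genome scan and candidate loci

The scan slides a fixed-S window one SNP at a time, rebuilding the MARH
*locally in each window* (a chromosome-global reference would let distant
regions leak into the classes). SNPs within ⌊S/2⌋ of a chromosome end are
skipped rather than given truncated windows, keeping the /S normalisation
uniform along the track. Empirical p-values are upper-tail ranks within the
chromosome-wide set of defined Svd values, ties sharing the larger
(conservative) p; the plotting flag marks Svd > 0 values in the top 1% of
positive values, and flagged SNPs within 20 SNPs of each other merge into
reported intervals (BED, 0-based half-open).

A caution on interpretation, measured on simulated sweep chromosomes: the
selected site ranks in the top decile of its own chromosome's Svd values in
~96% of replicates, but the single *arg-max* SNP is usually a linked
high-frequency neighbour rather than the selected site itself (within ±10
SNPs in < 20% of replicates even at ρ = 4Θ). Clusters of top-percentile
SNPs, not point maxima, are the meaningful scan signal.

Candidate-locus p-values compare each locus SNP's observed Svd with the
distribution of Svd at the corresponding column of simulation replicates
matched to the locus (sample size, Θ, ascertainment, selected-SNP index,
current frequency of the putative target), p = exceedance proportion over
≥ 1,000 replicates.

## Synthetic data vs real data

The generator reproduces the ingredients the validation battery needs:
coalescent genealogies with selection, recombination maps, frequency
spectra, ascertainment distortion. It does not emulate genotyping error,
phasing error (hook provided, phaser not included), gene conversion,
population structure or mosaic ancestry — so green tests here demonstrate
correctness of the statistic and calibration machinery under the stated
models, not robustness of Svd on any particular cohort. Real-data scans
should calibrate against the chromosome-wide empirical distribution (as the
scan module does) rather than simulated nulls, unless the simulation is
explicitly matched to the cohort's demography and SNP ascertainment.

## Known limitations

* Without recombination the analysis window is a single linkage block, so
  the HAC variance contrast and its null calibration scale together in S:
  detection power in this engine depends only weakly on window size under
  the ρ = 0 scenarios (the acceptance battery quantifies this). Window-size
  recommendations derived from it therefore apply to recombining data, where
  S genuinely trades signal span against haplotype breakup.
* Hotspots are parameterised as a per-bp rate multiplier over a fixed 2 kb
  interval. Other published conventions put the hotspot's *total* map
  length at a multiple of the background; at 100× the two readings diverge
  substantially, and power under very strong hotspots is sensitive to the
  choice.
* The sweep engine is a conditioned-trajectory structured coalescent; other
  engines in this model family differ in trajectory discretisation and
  finite-sites details, which is why calibrated power values carry a
  Monte-Carlo-plus-engine tolerance rather than a point guarantee.

## Numerical notes

Variances in double precision; test comparisons at 1e-9 absolute (1e-12
for the variance-oracle property). Infinite-sites positions are continuous;
exact duplicates (possible only through rounding) are nudged by 1e-9.
Mutation/recombination event sampling uses cumulative linear scans over
cached per-lineage totals; totals are zeroed when the lineage population
empties to keep float residue from stalling termination. Bitmask columns
are unpacked via byte serialisation, keeping the allele matrix construction
O(nS/8) rather than per-bit Python loops.
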