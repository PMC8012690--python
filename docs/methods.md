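# Methods

## Scope and model

`nat2kit` models the functional consequences of the four common *NAT2*
star alleles — \*4 (reference) and the reduced-function \*5, \*6, \*7 —
for the *N*-acetylation of eight substrate drugs (aminoglutethimide AGT,
diaminodiphenyl sulfone DDP, hydralazine HLZ, isoniazid INH, phenelzine
PZ, procainamide PA, sulfamethazine SMZ, sulfapyridine SP). The chain is:
signature-SNV genotypes → diplotypes → per-allele enzyme kinetics →
activity scores → clustered acetylator phenotypes → population phenotype
frequencies. Rare alleles (\*14, \*22, \*24) are deliberately outside the
supported universe: \*14 definitions can be *loaded*, but any scoring
path touching an allele without kinetic data raises an explicit
`UnsupportedAlleleError` rather than silently scoring it zero (a silent
zero would fabricate an ultra-slow phenotype).

## Diplotyping and EM haplotype frequencies

Star alleles are haplotypes over three signature sites (rs1801280,
rs1799930, rs1799931); \*4 is the all-reference pattern and each variant
allele carries exactly one alternate. Haplotype frequencies over the
2^k patterns are estimated from unphased dosages by the standard
multilocus EM: uniform initialization, E-step over all phase-consistent
haplotype pairs, M-step from expected pair counts, stopping when the
log-likelihood gain falls below `tol` (default 1e-10) or `max_iter`
(500). The log-likelihood is asserted non-decreasing at every iteration.
The procedure is deterministic — no random restarts are needed because
the complete-data likelihood for this problem is well behaved at k = 3.

Individual diplotypes maximize the product of haplotype frequencies over
phase-consistent configurations; the winning configuration's share of
total likelihood is exposed as `posterior`, and `ambiguous` is set
whenever competing configurations retain mass. Ties break on the
lexicographic canonical label, so calls are reproducible. Two policies
are worth stating plainly:

* **Compound haplotypes are a hard error.** If the most likely phase
  puts two signature variants in cis, the haplotype has no name among
  {\*4, \*5, \*6, \*7} and every downstream score would be wrong;
  `CompoundHaplotypeError` names the offending sites. In practice the
  EM assigns such patterns ~zero frequency in cohorts drawn from the
  four-allele universe, so double heterozygotes resolve to the trans
  configuration with posterior 1.
* **Missing dosages are not imputed.** Sites observed in nobody are
  dropped with a warning; individuals missing a retained site are
  excluded from the EM and reported.

## Kinetics

Each allele × drug × replicate curve is fit to the Michaelis–Menten
equation. Two estimators are provided:

* `lineweaver_burk` (default): OLS of 1/v on 1/[S] over points with
  [S] > 0 and v > 0; Vmax = 1/intercept, Km = slope/intercept. This is
  the estimator behind the shipped reference tables and is kept as the
  default for reproducing them. It is, however, statistically fragile
  under the multiplicative noise real velocity data carry: the
  regression is dominated by the noisiest low-velocity points and the
  intercept (1/Vmax) sits near zero, so parameter errors are large and
  the intercept can go negative (reported as `NonConvergentFitError`).
* `nls`: trust-region least squares on the untransformed curve with
  positivity bounds, initialized from the Lineweaver–Burk estimate when
  that is physical and from the data otherwise. Use this on noisy data.

Under the default simulation conditions (5% CV, four replicates,
per-drug concentration designs), the median relative error of the
replicate-averaged nls estimates stays below 10% for every allele × drug
(worst ≈ 6.5%, for the HLZ design whose maximum concentration is only
~1.7 × Km), while the Lineweaver–Burk medians range from ~8% to over
100%. The test suite asserts the nls recovery and benchmarks nls ≤ LB.

[S] = 0 rows are blank checks and never enter a regression. Velocities
at or below a configurable `signal_floor` are dropped with a warning;
modelling the instrument's detection limit itself is out of scope.

CLint = Vmax/Km is computed **per replicate and then averaged**
(mean ± SE, SE = SD/√n with n = 4 replicates by default). Mean-of-ratios
rather than ratio-of-means is what the internal arithmetic of the
reference tables reflects; see "Known discrepancies".

Allele contrasts use Tukey's HSD (`scipy.stats.tukey_hsd`) with the
letter convention a/b/c = p < 0.05 versus \*4/\*5/\*6. Zero-variance
groups yield degenerate p-values (1 for equal means, 0 otherwise) with a
`degenerate` flag instead of a crash.

## Activity scores

Allele score = CLint/CLint(\*4); genotype score AS = sum over the two
alleles. Scores are exact ratios kept at full precision internally;
reports round half-up to 3 decimals. Invariants enforced or tested:
AS is symmetric in allele order, AS(\*4/\*4) = 2 exactly, and
AS(x/x) = 2·(AS(\*4/x) − 1).

## Phenotype categorization

Per drug, the ten genotype scores are clustered by agglomerative
hierarchical clustering with the Ward-D2 criterion on Euclidean
distances (`scipy.cluster.hierarchy.linkage(..., "ward")`; merge heights
are exposed on the squared-distance scale to match the R `ward.D2`
convention). Leaves are sorted lexicographically before linkage so the
tree is invariant to input order.

The cluster count is selected from candidates {3, 4} (configurable) by
the **Krzanowski–Lai index**, KL(k) = |DIFF(k)/DIFF(k+1)| with
DIFF(k) = (k−1)^{2/p}·W(k−1) − k^{2/p}·W(k), p the dimensionality (1
here) and W the pooled within-cluster sum of squares; ties fall back to
mean silhouette width, then to the smaller k. The design question here
was genuinely open: on 1-D score profiles of this shape, global
compactness criteria are insensitive to exactly the distinction that
matters. Mean silhouette prefers k = 3 for *all* eight drugs and
Calinski–Harabasz prefers k = 4 for seven of eight, because whether the
slow tail splits into a distinct ultra-slow group barely moves either
statistic. The KL ratio measures the marginal W-reduction of that split
directly and recovers the published choice (k = 4 for HLZ/PZ/SMZ, 3
elsewhere) for all eight drugs, with decision margins from 1.03× (PA)
to four orders of magnitude (DDP). A dedicated test keeps the whole
80-label reproduction surface pinned.

Clusters sorted by decreasing mean AS are labelled RA, IA, SA for k = 3
and RA, IA, SA, USA for k = 4. In 1-D a Ward cut cannot interleave, but
the ordering consistency (min of a faster class > max of a slower one)
is asserted anyway.

## Population distributions

Phenotype frequency = sum of member-genotype counts / cohort size.
Proportions are exact rational arithmetic on integer counts; percentages
round half-up to 2 decimals at report time only. The shipped cohort
table covers the six printed population groups (Japanese n = 990; AFR
661, AMR 347, EAS 504, EUR 503, SAS 489); user-supplied subpopulation
counts use the same long TSV schema (population, genotype, count).

## Synthetic data: what it emulates, what it does not

`simulate_cohort_hwe` draws two alleles i.i.d. per individual from a
star-allele frequency vector (Hardy–Weinberg / random mating) and emits
both the true diplotypes and the implied dosage rows. It emulates
genotype-frequency structure only: no linkage to non-signature variants,
no genotyping error, no missingness, no population substructure.
Passing round-trip tests therefore show that phasing and calling are
correct *given* the four-allele universe, not that they are robust to
assay artefacts.

`simulate_kinetic_dataset` generates v = Vmax·[S]/(Km+[S]) ×
LogNormal(mean 1, CV `cv_noise`) over the per-drug concentration designs
(nine levels including the 0 blank, e.g. 0–1000 µM for AGT, 0–10 µM for
HLZ). Defaults are the study conditions: published (Km, Vmax) truth for
all 32 allele × drug pairs, four replicates, 5% CV. Multiplicative
lognormal noise (not additive Gaussian) is chosen because velocities are
positive peak-area ratios whose scatter scales with signal; the single
`cv_noise` knob deliberately does not decompose biological from
technical variance. Both generators are driven by one integer seed
through a local `numpy` Generator; no global random state is touched.

At these conditions the full synthetic round trip (simulate → fit →
score → cluster) reproduces the published phenotype labels for 7 of 8
drugs at the fixed seed used in the tests; DDP is the boundary case —
its \*7 scores sit nearest a cluster margin, so a noise draw can move
\*7/\*7 out of the rapid cluster.

## Known discrepancies in the reference tables

The published kinetic table prints mean ± SE of per-replicate estimates,
but not the replicates. Consequently the ratio of printed means does not
exactly reproduce the printed CLint: 26 of 32 rows agree within 2%, but
six rows differ by 2.9–4.8% (worst PZ \*6), and one (AGT \*6) even flips
the third decimal. Propagated into activity scores, rebuilding all 80
genotype scores from the printed CLint means matches 62/80 within 0.005
but leaves a worst absolute error of 0.113 (DDP \*7/\*7, printed 1.564
vs 1.451 rebuilt), concentrated in DDP and PZ. Clustering the *rebuilt*
scores therefore flips DDP and SMZ labels, while clustering the
*published* scores reproduces all 80 labels exactly. The package treats
the published scores as the reproduction surface for phenotypes, keeps
the rebuilt-score path available (it is what you get from your own raw
data), and pins both behaviours in tests at their measured envelopes.

## Numerical and interface choices

* Report rounding is half-up (`decimal`), 3 decimals for scores,
  2 for percentages; comparisons in tests use unrounded values.
* All tables are tab-separated UTF-8 with a single header row; a JSON
  companion carries full precision; reruns are byte-identical apart
  from the timestamped log line.
* VCF input is matched by rsID in the ID column, dosage comes from GT
  (phase ignored), multi-allelic signature records are rejected.
* Genotype labels are canonical `*a/*b` with numerically sorted alleles.

## Limitations

* The allele universe is {\*4, \*5, \*6, \*7}; sub-allele distinctions
  (\*5A/\*5B, \*6A, \*7B) and rare alleles are out of scope.
* Cluster-count selection is validated on the published score profiles
  and on perturbations of them; profiles of a very different shape may
  need a different candidate set or criterion.
* Population cohorts are opaque count tables; no association testing,
  admixture handling or clinical outcome modelling is attempted.
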