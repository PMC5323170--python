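# Methods

## Scope and data model

driverlens operates downstream of variant calling: its inputs are annotated
somatic variant tables (one row per SNV/indel per patient, with read
counts, predictor scores and population allele frequencies), SEG-like CNV
tables, a clinical table (sex, maturation subtype, relapse, purity), and a
COSMIC-like mutation catalogue. All coordinates are 1-based inclusive.
Missing scores and frequencies are explicit missing values, never 0: a SIFT
or CHASM score of 0 is maximally damaging, so silent coercion would invert
its meaning.

## Predictor thresholds

SIFT calls a variant damaging at score ≤ 0.05 (boundary inclusive);
PolyPhen2 is benign below 0.447, possibly damaging in [0.447, 0.909] and
damaging strictly above 0.909; MutationTaster is damaging strictly above
0.9. CHASM p-values are adjusted with Benjamini–Hochberg over the cohort's
missense variants that carry a score, and a variant is a predicted driver
at FDR ≤ 0.20. Cohort-wide adjustment is the default (the conservative
reading; a per-patient scope is available). A missing score abstains: it is
never counted for or against a consensus.

In the ≥2-of-3 consensus of rule i, PolyPhen2 counts as a damaging vote at
*possibly damaging* or above, because both categories are predictions of
damage under the tool's own nomenclature; a strict switch
(`polyphen_strict=True`) restricts the vote to the damaging category.

## Nomination rules

The population prefilter removes variants with any of the 1000 Genomes /
ESP / ExAC frequencies strictly above 0.01; a missing frequency keeps the
variant (absence of evidence of commonness). The four rules are described
in the README; implementation decisions worth recording:

* Catalogue recurrence is matched at protein-change granularity (the level
  at which hotspots are reasoned about, e.g. p.R35L), with a default
  minimum of 2 recorded samples and an optional hematopoietic-only
  restriction.
* Rule ii's "located in a tumor suppressor" uses the 20/20 classification
  by default; a curated gene list can be supplied instead by classifying
  against a different catalogue.
* Rule iv requires ≥ 2 events in ≥ 2 distinct patients by default — two
  hits in one patient are more likely a local artifact — with a
  same-patient switch for the permissive reading. It also requires the
  gene to be absent from an explicit, user-supplied known-gene list; no
  hidden bundled list decides novelty.
* An event satisfying several rules is emitted once, carrying every
  evidence tag and the lowest-numbered rule as primary. Output order is
  canonical (sorted), so nomination is invariant under input permutation.
* CNV events nominate one call per qualifying gene on the segment.

## Gene roles (20/20 rule)

Inactivating classes are nonsense, frameshift indel and splice site;
in-frame indels are not inactivating. A gene is a TSG when its
sample-weighted inactivating fraction is ≥ 0.20; an oncogene when the
fraction of missense samples at residues recorded in ≥ 3 samples is ≥ 0.20
while the inactivating fraction stays below 0.05. Genes with fewer than 10
recorded samples remain unclassified rather than being noisily labelled.
All five constants are parameters with these defaults.

## Clonality model

With tumor purity ρ, a clonal heterozygous mutation on a diploid autosome
is expected at VAF = ρ/2: one mutated copy among the two tumor copies,
diluted by normal cells carrying two reference copies. Hemizygous
sites (male X, one-copy regions) and homozygous sites after LOH both reduce
to expected VAF ρ. The purity-adjusted fraction is observed VAF divided by
this expectation; the clonal/subclonal cutoff is 0.7, chosen so that the
canonical cohort-scale anchors (VAF ≈ 0.48 clonal, ≈ 0.33 subclonal at
purity near 1) fall on the intended sides, and exposed as a parameter.
Female X-linked mutations observed near VAF 1 are handled by the LOH/
X-inactivation state rather than special-casing. A missing purity defaults
to 1.0 and is logged. RNA support for a mutated allele requires ≥ 2
alt-supporting RNA reads and RNA VAF ≥ 0.05.

## Exact statistics

* **Fisher exact, two-sided** — the p-value sums hypergeometric point
  probabilities of all margin-consistent tables whose probability does not
  exceed the observed one (with 1e-7 relative tie tolerance), computed in
  log space from log-factorials. This is the convention of R's
  `fisher.test`; the alternative doubling-the-one-tail convention does not
  reproduce standard published two-tailed values and is deliberately not
  offered.
* **Mann–Whitney U** — U from midrank sums. For n1+n2 ≤ 12 the null is the
  full enumeration of all C(n1+n2, n1) labelings of the pooled sample,
  which remains exact under ties. For larger tie-free samples the classical
  exact null distribution of U is computed by the Gaussian-binomial
  recursion (the behavior of R's `wilcox.test` for n < 50, which matters
  for cohort-scale contrasts such as 26 vs 6). Otherwise a normal
  approximation with tie-corrected variance and 0.5 continuity correction
  is used. Two-sided p is 2·min(P(U ≤ u), P(U ≥ u)), clamped to 1.
* **Benjamini–Hochberg** — step-up q-values q(i) = min over j ≥ i of
  p(j)·m/j in sorted order, capped at 1, returned in input order.

The association report applies no multiplicity correction by default,
matching common practice for a handful of pre-specified cohort tests; a BH
column can be switched on.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes, at the
annotated-table level:

* 30 patients by default, male fraction 2/3; subtype probabilities
  5/30 immature, 2/30 ETP, 13/30 mature, 10/30 unclassified; relapse
  probabilities 5/7 for immature and ETP, 1/13 for mature, 0.2 for
  unclassified — matching the cohort composition the association tests are
  calibrated against.
* Purity uniform on (0.80, 0.98); sequencing depth negative-binomial with
  mean 150 and dispersion 10 (ultra-deep targeted panels are deeper; this
  mean keeps binomial VAF noise realistic while most sites clear the
  depth-100 bar used in clonality benchmarking).
* Planted drivers per gene follow independent per-patient Bernoulli draws
  at the preset frequencies (NOTCH1 0.50, CDKN2A deletion 0.55, PHF6 0.267,
  FBXW7 0.133, JAK3 0.133, NRAS 0.10, U2AF1 0.10, MED12 0.10, USP9X 0.067,
  KDM6A 0.034, JAG2 gain 0.067). Clonal events draw alt counts
  Binomial(depth, expected VAF) at the copy-state expectation; subclonal
  (Ras-like, U2AF1-like) events scale the expectation by Uniform(0.1, 0.6).
  X-linked drivers are hemizygous in males and LOH-state in females, both
  giving VAF near the purity.
* Predictor scores: drivers draw SIFT ~ Beta(1, 20), PolyPhen2 ~
  Beta(20, 2), MutationTaster ~ Beta(20, 2), CHASM p ~ Beta(1, 30);
  passengers draw the mirrored Betas. These families are invented; their
  only contract is separation between the driver and passenger populations
  sufficient for recall/false-positive benchmarking. Scores are emitted
  for the classes the corresponding tools score (all four for missense,
  SIFT/MutationTaster for nonsense and splice site, none for indels and
  silent variants).
* Passengers arrive at Poisson rate 27 per patient (the scale of somatic
  SNV/indel burdens in pediatric leukemia exomes) over an 18,000-gene
  neutral pool, with a class mix dominated by missense/synonymous/other;
  2% of passengers carry a population frequency above 0.01 to exercise the
  prefilter.
* The catalogue is constructed so each planted TSG has ~86% truncating
  sample mass and each planted oncogene a dominant recurrent hotspot with
  ~3% truncating mass; novel genes (U2AF1, MED12, USP9X analogues) are
  omitted from both the catalogue and the known-gene list, so their only
  route to nomination is predictor evidence or cohort recurrence — exactly
  the situation that motivates rule iv.
* Randomness: a single seed feeds a splittable per-patient stream
  (`numpy` SeedSequence spawning), so output is byte-identical for a fixed
  seed and adding a patient does not perturb the other patients' draws.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline's decisions depend on
(VAF/purity coupling, score separation, catalogue composition, cohort
recurrence), not sequencing physics: there are no alignment artifacts,
strand biases, contamination, or correlated mutational processes, and
passenger genes are an abstract pool rather than real loci. Passing
benchmarks on synthetic cohorts therefore demonstrates the pipeline's
internal correctness and calibration under its stated assumptions, not its
performance on any real tumor cohort.

### Benchmark measurement conventions

Driver recall counts a planted driver as recovered when any rule nominates
it. The passenger false-positive rate counts a passenger only when it is
nominated with evidence beyond the bare cohort-recurrence tag: rule iv is a
cohort-size-dependent screen (in a 2,000-patient benchmark essentially
every pool gene is hit in ≥ 2 patients, which says nothing about the score
model), so the false-positive control is measured against the score- and
role-driven rules i–iii, while rule iv's behavior is exercised separately
at its design scale of ~30 patients. Clonal-label recovery is measured on
planted-clonal driver SNVs at depth ≥ 100 using the true copy state.

## Numerical and degenerate-input choices

All-zero contingency tables return p = 1 with a warning. Empty sample
groups are usage errors. BH on an empty vector returns an empty vector.
The Fisher tie tolerance (1e-7 relative) guards against floating-point
noise when two tables have equal probability. The exact Mann–Whitney
enumeration bound (n1+n2 ≤ 12) and the tie-free exact bound (n1·n2 ≤
10,000) balance exactness against cost and are parameters. Variant rows
violating invariants (alt_count > depth, scores outside [0, 1]) are
rejected with row-level diagnostics rather than aborting the table read;
structural problems (missing columns, duplicate patient ids) abort.

## Known limitations

* Somatic-confirmation thresholds for tumor/normal pileup screening
  (tumor VAF ≥ 0.05; normal VAF ≤ 0.01 and ≤ 1 alt read) are conventional
  ultra-deep screening defaults, not a reconstruction of any specific
  caller's internals.
* The 20/20 constants beyond the two 20% cut-offs (truncating ceiling
  0.05, residue recurrence ≥ 3, minimum catalogue evidence 10) follow the
  published rule's common usage but are ultimately conventions; all are
  exposed.
* Clonality is a threshold on a point estimate; no subclonal deconvolution
  or mixture modelling is attempted, and read-count uncertainty is not
  propagated into the label.
* Rule iv's novelty depends entirely on the supplied known-gene list and
  catalogue; with an incomplete list, recurrent passengers will surface as
  "new candidate genes", which is by design (they did in the motivating
  study too — that is what downstream validation is for).
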