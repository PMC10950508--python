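# Methods

This note documents the models, statistical conventions and design choices
behind `pgxddi`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with which
defaults, and what the validation does and does not demonstrate.

## Data model

Genotypes are held as a samples × variants matrix of alternate-allele
dosages {0, 1, 2} with a missing sentinel (−1). Only biallelic SNVs are
loaded from VCF; multiallelic records and indels are skipped (annotation
tables are keyed per rsID/alt pair, and splitting multiallelics would
introduce an ambiguity the downstream statistics never resolve), and
mitochondrial sites are excluded at load because population reference
panels cover them inconsistently. Phase is ignored everywhere: every
statistic in the package is a function of dosage. Sex chromosomes are
treated as diploid. All skipped/dropped record classes are counted and
logged, never silently discarded.

Clinical annotations follow the PharmGKB shape: an allele identifier (rsID,
star allele, or HLA allele; the type is inferred from identifier syntax and
must agree with an explicit type column when one is present — loading
fails fast on ambiguous curation), a gene, a drug, an evidence level
(1A–4), and a risk allele. Records are deduplicated on
(allele_id, drug, level), so one variant–drug pair may legitimately appear
at two evidence levels. Drug–gene catalogs are sets of
(drug, role, gene) triples with the four DrugBank-style roles (carrier,
transporter, enzyme, target); gene symbols are upper-cased and duplicates
removed; no alias resolution is attempted (determinism without external
dictionaries).

## Landscape counting

A sample *carries* a SNP annotation iff its dosage of the risk allele is
≥ 1 (when the annotated risk allele is the reference base the dosage is
inverted); a star/HLA annotation iff either diplotype allele equals the
risk allele. Missing genotypes count as non-carrier and are logged.
Counting is carrier-based — a variant counts once whether one or two risk
copies are present — because per-drug risk summaries in this literature
count "variants carried"; dosage weighting is available behind an explicit
flag (`weight_by_dosage`).

Summaries report the median (numpy linear interpolation, giving
half-integer medians for even cohorts), min/max range, quartiles by the
midpoint-exclusive (Tukey) convention — the sorted data are split at the
median, the middle element of an odd-sized sample belongs to neither half,
and Q1/Q3 are the medians of the halves — and the carrier fraction
(share of samples with count ≥ 1). Other quartile conventions (e.g. the
linear-interpolation quantiles of numpy) can differ by up to one count
unit on small samples; the exclusive convention was fixed and is tested.

The evidence-level filter of the landscape is a **mandatory explicit
parameter** with no hidden default: whether weak-evidence (level 3/4)
records enter materially changes the landscape, and silently defaulting
either way would be misleading.

## Fisher exact allele-frequency comparison

Per shared variant, the 2×2 table of (alt, ref) allele counts × population
is tested two-sided under the minimum-likelihood convention: the p-value
sums hypergeometric point probabilities no larger than the observed
table's (with a ~1e-7 relative tie tolerance). A table with a zero margin
is uninformative; p = 1 by convention, logged. No multiple-testing
correction is applied by default — the significance flag is a bare
p < α — with Benjamini–Hochberg available behind `bh_correct=True`.
The implementation delegates to `scipy.stats.fisher_exact`; the test suite
and the acceptance script verify it against an independent exhaustive
enumeration oracle to 1e-10.

## Weir–Cockerham F<sub>ST</sub>

Per biallelic site, the two-population Weir & Cockerham (1984) variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from observed (non-missing) sample
sizes, allele frequencies and heterozygote proportions. Components are
kept as computed — negative values are not clamped. The pairwise statistic
is the ratio of sums Σa / Σ(a+b+c) across sites (the weighting of PLINK's
Fst implementation); the mean of per-site ratios is also reported. Sites
monomorphic across the pooled pair, or with fewer than two observed
genotypes in either population, are excluded from the sums; no further
site filters (MAF, missingness) are applied, and this is deliberate —
filtering policy belongs to the caller. Missingness is handled per site
per population through observed genotype counts.

Validation: a fixed-difference panel gives exactly 1; a cohort against a
copy of itself concentrates near 0 (|F̂| < 0.01 at 2,000 sites); the
components agree with an independent symbolic (sympy) evaluation of the
textbook expressions on random inputs; and the estimator recovers the
Balding–Nichols divergence parameter within ±0.02 for F ∈ {0.05, 0.1, 0.2}
at 500 diploids per population and 5,000 sites.

## Synthetic-data generator

The generator defines the conditions under which the package is validated.

* **Genotypes** follow the Balding–Nichols model: per variant an ancestral
  frequency p is drawn uniformly on [0.05, 0.95] (bounded away from the
  edges so monomorphic sites do not dominate; boundary draws are redrawn),
  each population's frequency is Beta-distributed with mean p and variance
  p(1−p)F, and genotypes are Binomial(2, frequency). The model's expected
  Weir–Cockerham F<sub>ST</sub> is approximately F, which provides the
  closed-form recovery target. It deliberately omits linkage
  disequilibrium, demography beyond a single-F star split, and realistic
  haplotype structure.
* **Catalogs** combine Bernoulli background links (per-role density) with
  planted shared elements for designated drug pairs; the set of truly
  interacting pairs is then recomputed by brute-force set intersection
  over the emitted catalog, so background-induced overlaps are part of the
  truth, not noise.
* **Annotations** attach risk alleles to real cohort variants and record
  per-sample carrier counts directly from the genotype matrix, giving the
  landscape stage an exact planted truth.
* **Diplotypes** are drawn from stated per-gene allele frequencies
  (defaults mirror East-Asian-like CYP2C19 allele frequencies: *1 0.65,
  *2 0.30, *3 0.05).

All randomness flows from one integer seed through named numpy generators.
Passing tests on these inputs demonstrates algorithmic correctness — exact
counting, exact set logic, unbiased estimation under the stated model —
not robustness to the messiness of real cohort data (batch effects, call
errors, annotation curation noise).

The default demonstration conditions (pipeline `SimulationBlock` and the
analysis scripts) use 3 populations of 120–160 diploids, 400–500 variants,
F = 0.05, 20 drugs over 60 genes at role density 0.03 with planted
interacting pairs, and 8 annotations for each of 14 drugs. The validation
experiments use the sizes stated above for each statistic (up to 1,000
samples for landscape truth and 2 × 500 × 5,000 for F<sub>ST</sub>
recovery), chosen so each quantity's sampling error is well inside its
stated tolerance.

## Candidate-variant filter

The filter is a conjunction of four audited flags per variant:
nonsynonymous exonic class; gene in the CTET catalog of the active drug
list (no genome-wide scan); ≥ 2 damaging votes among SIFT ("damaging"),
PolyPhen-2 ("damaging"/"probably damaging") and MutationTaster
("disease causing"), with a missing call abstaining; and cohort allele
frequency **strictly** greater than the threshold (default 0.01 — "> 1%"
is read literally, and the boundary is unit-tested). The "at least two"
reading of the voting rule was adopted over the alternative "exactly two"
reading; with three predictors the two differ only for unanimous calls,
which any deleteriousness screen should keep. Predictor execution is out
of scope: calls arrive as annotation tables.

## DDI model

The element universe is recomputed per analysis from the analysed drug
set, so d — and therefore every Russell–Rao value S = xᵀy/d — is
**universe-relative**: adding unrelated drugs to an analysis changes the
S values but can never flip an S > 0 decision (property-tested). S is not
a severity measure and no severity field is emitted.

The DDI flag is gated on the hybrid (all-CTET) vector: it is the only
vector type covering every sharing mode, and the per-role similarities are
reported alongside. The hybrid universe is keyed by (role, gene) by
default, so a gene serving two roles contributes two elements and hybrid
positive matches decompose exactly over roles; the gene-only keying (a
gene shared under *different* roles counts as a match) is available as
`hybrid_keying="gene"` since curated catalogs do not always distinguish
roles consistently.

Drugs with no catalogued elements (zero vectors) are eliminated before
scoring and reported. Regimen counting runs over the union of the drug
sets with each drug entering once; every DDI pair is bucketed exclusively
(both in A → within-A; else both in B → within-B; else cross), so
union = within_a + within_b + cross holds identically, including for
overlapping regimens (a pair inside the overlap is credited to the first
regimen).

The drug–gene network collapses roles onto edges (edge attribute lists the
roles); a gene's degree is the number of distinct linked drugs, a drug's
degree its number of distinct pathway genes.

## Pipeline determinism

A run is a pure function of (config, seed): stage outputs are sorted
canonically, floats are formatted with a fixed `%.10g`, the run log
carries no timestamps, and per-stage seeds are derived arithmetically from
the master seed. Two runs with the same config are byte-identical, which
is asserted in the validation suite. Stage failures abort with the stage
name and write a machine-readable `error.json`.

## Known limitations

* No linkage disequilibrium or realistic demography in the generator; the
  F<sub>ST</sub> recovery target is model-matched by construction.
* Star-allele and HLA handling consumes external diplotype calls; the
  package performs no calling, phasing or imputation.
* Multiallelic sites are skipped, not split.
* The Fisher comparison tests each variant marginally; no per-site
  F<sub>ST</sub> significance, haplotype statistics or admixture modelling.
* Catalog quality bounds DDI prediction: the model finds exactly the pairs
  that share a catalogued element — no mechanism, severity or direction.
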