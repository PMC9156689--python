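# Methods

## Design and coordinates

A study is a set of translocation lines, each varying one chromosomal
segment, plus a whole-ploidy series and a B-chromosome control pair.
Internal coordinates are 1-based inclusive (GFF convention); BED input is
converted on read and round-trips exactly. A feature is **cis** to a line
iff its locus overlaps the varied interval by ≥ 1 bp on the same chromosome.
Breakpoint-straddling loci are therefore cis: part of their sequence has
varied copy number. Segment length is `end − start + 1` bp. The partition
is exhaustive and exclusive by construction and is property-tested against a
per-basepair brute-force check.

## Normalisation and filtering

Counts are normalised to reads per million mapped reads:
`RPM = count / library_size × 1e6`. Library size is the externally supplied
total of mapped reads when available (the analysed feature matrix is
typically a small fraction of an sRNA library), else the column sum.
Per comparison, features whose mean RPM over the pooled experimental and
control replicates is **< 0.5** are excluded before testing, so the BH
family is exactly the tested set; the boundary value 0.5 is kept. The filter
is monotone in its threshold. RPM deliberately does not measure expression
per cell: whole-ploidy genotypes scale per-cell expression and transcriptome
size together, which cancels under RPM, and the pipeline expects (and
verifies on synthetic data) no differential calls in a pure ploidy series.

Replicate QC is report-only: PCA on centred, unscaled RPM over a
comparison's samples flags any sample whose PC1 or PC2 lies more than 2 SDs
from the mean (run per comparison by default; a global run is a caller
choice), and every replicate pair gets a Pearson R with two-sided P, flagged
at P ≥ 0.05 or when R is undefined for a constant profile. Flagged samples
are reported, never dropped automatically; sample exclusion lists are
accepted as input (raw-read QC is upstream of this package).

## Differential expression

The NB exact test conditions the two group totals on their sum after
equalising libraries by linear scaling of counts to the rounded
geometric-mean library size (a simpler, oracle-checkable alternative to
quantile adjustment; adequate at the count depths analysed here and
deliberately not a numerical clone of any particular DE package). With
group sizes n_A, n_B and dispersion φ, group totals are NB(n·μ, φ/n); the
null mean is the grand total over total library count, and the two-sided
p-value is the probability mass of all splits no more probable than the
observed one (minimum-likelihood two-siding, the standard choice for exact
conditional tests; ties are included with a 1e-12 relative tolerance). At
φ = 0 the conditional distribution is exactly binomial with the
library-size share as success probability — an identity the tests check to
1e-9.

The common dispersion maximises the summed conditional log-likelihood of
replicates given their per-feature sums (the negative-hypergeometric
identity removes μ), bounded in [1e-6, 20] on the log scale with an explicit
Poisson-limit comparison. Tagwise dispersions are per-feature moment
estimates shrunk linearly toward the common value with weight 0.7 by
default (1.0 = fully common); a single-feature matrix degenerates to the
common value. The default testing mode is common dispersion.

P-values are BH-adjusted per comparison; FDR < 0.05 defines the
differentially expressed set, with direction from the sign of
log2(mean RPM experimental / mean RPM control). The tetraploid-vs-triploid
contrast crosses genetic backgrounds and shares a euploid diploid reference,
so it uses a two-sample two-sided Student's t test on per-replicate
log2 ratios to the reference-group mean (unpaired; a 0.5 pseudocount guards
zero replicates); zero-variance equal-mean inputs give p = 1.

## Dosage-response typology

For a comparison at dosages (d_e, d_c) the reference fold changes are
direct = d_e/d_c and inverse = d_c/d_e, exact rationals internally and
rounded to two decimals only for reporting (2.0/0.5 for 1D/2D and h2D/h1D,
1.5/0.67 for 3D/2D, 2.0/0.5 for 4D/2D, 1.33/0.75 for 4D/3D). Per-feature
fold changes are ratios of group-mean RPM; a zero control mean makes the
ratio undefined and excludes the feature from medians (no pseudocounts —
the 0.5-RPM filter bounds denominators in practice). The median of trans
ratios summarises each comparison; medians are clustered per series with an
exact 1-D k-means (k = 2): optimal 1-D clusters are contiguous in sorted
order, so a dynamic program over split points finds the global
within-cluster-SSE optimum deterministically (verified against exhaustive
partition search and random-restart Lloyd).

Features differentially expressed in the 1B/0B control are removed from all
aneuploidy interpretation before classification and trend summaries, since
their response cannot be attributed to the essential chromosomal segment.

Classification uses, per line, the comparisons against the background
euploid control (1D/2D, 3D/2D, 4D/2D, h2D/h1D; the progressive 4D/3D
contrast is reported but not classified). With S the set of comparisons
significant at FDR < α (α = 0.05 default) and "alignment" the product of the
call's direction and the dosage-change direction:

- **direct dosage / positive trans** — every call in S aligned, |S| ≥ 1;
- **negative dosage / inverse trans** — every call opposed;
- **increased / decreased** — all calls the same direction, with at least
  one significant dosage-reduced and one dosage-increased comparison;
  increased/decreased is checked before the linear labels, which the
  mutually exclusive conditions make order-insensitive;
- **compensation** (cis only) — S empty and every fold change within
  [0.8, 1.25] (band configurable as [1/c, c], c = 1.25);
- **mixed** — any other pattern of significant calls; in practice conflicts
  between the diploid- and haploid-background series;
- **unclassified** — no evidence, or S empty with the compensation band
  violated.

The source study never prints its classification rules; this decision table
is a formalisation of its response categories chosen to be testable: a
27-case hand-enumerated truth table over {up, down, ns}³ pins the trans
typology. Trans features are eligible for classification when significant
in all of a line's available comparisons except at most one (significance in
the disomy comparison alone suffices when it is the only one available);
ineligible features are reported unclassified, not misclassified. One open
choice: whether increased/decreased should accept a single-sided significant
pattern. This implementation requires both directions; a feature significant
only in dosage-increased comparisons with consistent direction is labelled
by alignment (positive/negative) instead.

## miRNA–target correlation

Interaction records carry source tags (prediction, degradome) and a mode;
inhibition-mode rows are dropped (expression correlation is only
interpretable for cleavage), prediction rows with expectation score > 3 are
dropped, and duplicate pairs merge their sources. Correlations are Pearson
R with two-sided P (t transform, n − 2 df) over **per-genotype mean** RPM —
genotype means avoid pseudo-replication and match the averaging used for
ratios. Global scope uses all genotypes present; local scope restricts to
one line's dosage series (diploid plus haploid branches). Series with fewer
than 3 genotype classes, constant series, and expression-filtered features
are excluded with explicit reasons. No multiple-testing adjustment is
applied by design (a BH option exists, off by default). The
source-intersection summary counts interactions significant with both
evidence tags, split by sign of R.

## Synthetic data generator

The generator emulates the study structure: per line, diploid-background
dosages {1, 2, 3, 4} and haploid-background {1, 2} sharing euploid controls,
a 1X–4X ploidy series, a 0B/1B pair, and 2–4 replicates per genotype
(default 3). Baseline abundances are a lognormal mixture on the RPM scale —
85% around 20 RPM (sdlog 1.0), 15% around 0.3 RPM — so 10–20% of features
fall below the 0.5-RPM filter and the filtering path is exercised. Library
sizes are lognormal with mean 5×10⁶ and CV 0.2, chosen as a realistic mapped
depth that keeps exact-test enumeration cheap at these feature counts.
Counts are NB(expected RPM × library/1e6, φ), φ = 0.05 by default.

Each feature carries an archetype with closed-form per-genotype mean ratios
relative to its background euploid (b = background ploidy, d = its home
segment's dosage): direct d/b; negative b/d; compensation 1; trans
positive/inverse d/b and b/d of the home line; increased/decreased
exp(±δ·1[d ≠ b]) with δ = log 1.5 (chosen for classifier testability — the
study gives no magnitude); mixed = direct on the diploid background, inverse
on the haploid one; background features 1 everywhere; B-responsive decoys
×2 when a B chromosome is present (default 2 such features, matching the
two control-responsive features the design must be able to exclude). Trans
archetypes respond to their **assigned** line only — in any other line's
comparisons they are nulls — so per-comparison trans medians trend toward
the inverse reference only in configurations where most trans features are
assigned to the compared line. Ploidy genotypes have d = b, hence ratio 1
for every archetype: the RPM-scale means are ploidy-invariant, encoding the
transcriptome-size cancellation. Cis loci are placed inside their home
segment with home lines drawn proportional to segment length (so cis counts
track segment size); trans and gene loci are placed below every segment
start. Coupled targets follow
baseline × (miRNA genotype mean / miRNA baseline)^(s·γ) with γ = 0.8 and
sign s negative for 60% of couplings by default; half the genes are coupled
(to response-carrying miRNAs, so the coupling is identifiable), half are
decoys; the interaction table includes inhibition-mode and weak-prediction
rows that the loader must drop. A fixed seed makes every output
byte-identical.

What the generator does *not* emulate: read-level artifacts (adapter,
quality, multimapping), hairpin annotation, genuine genomic miRNA cluster
spacing, genetic-background expression differences beyond the 4X/3X
design, and correlated dispersion structure across features. Passing tests
establish that the statistics recover the effects they model under NB noise
at realistic depths — not that real sRNA libraries satisfy those modelling
assumptions.

## Problem sizes and numerical choices

The validation suite runs at desk scale chosen for tight Monte-Carlo error:
null calibration at 1000 features × 3 replicates (type-I error within 3
binomial SDs of α at α ∈ {0.01, 0.05}); classification recovery at 200
features per archetype over 2 lines (recovery is measured on the
classifiable set, as defined above, per archetype); coupling sign recovery
over 200 simulated studies of the 12-genotype single-line design; exact-test
oracle equivalence over all totals ≤ 200 at dispersions {0, 0.05, 0.2, 1};
k-means optimality against exhaustive search for n ≤ 12 and against 100
Lloyd restarts on 1000 random inputs. Exact-test ties are grouped with a
1e-12 relative tolerance; the k-means DP breaks ties by the first optimal
split point, making output independent of input order; classifier output is
invariant to evidence order and replicate relabelling.

## Known limitations

- Exact numeric concordance with any specific DE package is a non-goal; at
  3 replicates and dispersion ≥ 0.05, 1.5-fold effects are power-limited
  (per-comparison detection ≈ 50–60% at raw 0.05), which bounds what any
  method can recover at that design point.
- The trans typology's eligibility rule follows the study design it mirrors;
  single-comparison evidence is deliberately left unclassified rather than
  over-interpreted.
- Local correlations pool a line's diploid and haploid branches; RPM-scale
  background differences cancel only insofar as both series respond to the
  same dosage signal.
- Real deposited datasets (and hence the study's dataset-level counts) are
  out of scope; the supplementary-style recomputation path is exercised on a
  synthetic stand-in table.
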