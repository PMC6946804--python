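# Methods

## The model and procedures

**Gene-family abundance and expansion scoring.** The unit of analysis is a
gene family (an orthologous-cluster assignment supplied as input; the
package never annotates genes itself). For genome *g* and family *f*,
relative abundance is A(f, g) = 100 · n(f, g) / N(g), the percent of the
genome's N(g) genes annotated to *f*; over a genome's complete family
universe the columns sum to 100. "Most abundant" families are ranked by
mean relative abundance across genomes (a symmetric, scale-free statistic
when subgroups contribute unequal genome counts), ties broken
lexicographically so the ranking is total. Z-scores are computed per family
across genomes — the question is *which genomes* are enriched for a family —
with the sample (n−1) standard deviation; constant rows are defined as
all-zero rather than an error because subset matrices routinely contain
flat families. Family–family association uses Pearson's r across genomes;
correlations of constant profiles are reported missing (NaN), never imputed.
Subgroup expansion is operationalized as a mean-abundance ratio
score(f, s) = (mean_in + ε) / (mean_out + ε) with ε = 0.01 (percent
abundance). The pseudocount keeps absent families at score 1 and bounds
scores of families missing outside the subgroup; raw maximum copy counts
are reported alongside so users can apply their own copy-number cutoffs.

**Chiral-complexity enzyme model.** A compound with *n* chiral centers has
2^*n* stereoisomers. If each stereoisomer needs its own degradative enzyme
the requirement is 2^*n*; if a racemase is available for every center the
stereoisomers interconvert and *n* + 1 enzymes suffice (one degradative,
*n* racemases). The model is analytic; the inequality 2^*n* ≥ *n* + 1 with
equality only at *n* ∈ {0, 1} is asserted as a property.

**Fragment recruitment.** Alignments are ingested in a configurable
BLAST-outfmt-6 tabular dialect. The identity filter retains alignments at
or above the cutoff (default 80 %); an optional mask (BED3, one record per
genome region, intended for rRNA genes whose conservation inflates
recruitment) disqualifies any alignment overlapping a masked interval by
even one base — conservative and cheap to verify. Coordinates are
normalized at parse time to 0-based half-open. Multi-mapped reads count
once per (read, genome): best bit score when the dialect provides one,
else first occurrence, with the deduplication logged. Two normalizations
are computed because both are in common use: the primary, size-free
fraction R(g, s) = Σ aligned bases / total sample bases, and a secondary
per-Mbp variant R/size(g) · 10⁶; callers choose explicitly.

**Single-copy-normalized enzyme depth trends.** Within a focal taxon and
sample, the abundance of an enzyme family is the count of taxon genes in
that family divided by the count of taxon genes hitting any cluster of a
single-copy ortholog panel. The denominator counts gene *occurrences*, not
distinct clusters, so it scales with both sequencing depth and taxon
abundance and the ratio approximates mean per-cell copy number. A zero
denominator yields a missing value with a warning — never 0 or infinity.
Depth correlations are Pearson's r on (value, depth) with pairwise deletion
of missing samples (counts logged) and a two-sided p-value from the
t transform with n − 2 degrees of freedom; depth enters untransformed in
meters by default, with a log-depth option behind a flag since no transform
is canonical. Sample selection keeps samples whose focal-taxon read
fraction is at least the threshold (default 1 %, inclusive).

**Mass-difference statistic.** FTICR-MS resolves DOM peak pairs whose
spacing equals an elemental mass difference. Peaks are treated as neutral
monoisotopic masses (charge deconvolution is upstream); within a sample,
unordered pairs (a, b), b > a, are counted when |(b − a) − Δ| ≤ tolerance,
with Δ(O) = 15.994915 Da and Δ(C) = 12 Da exactly (IUPAC monoisotopic
values). Tolerance defaults to 1 ppm of the heavier peak, reflecting FTICR
mass accuracy; an absolute-Da mode is available. Intensities are ignored —
the statistic counts observations. The per-sample O:C pair-count ratio is
missing when C pairs are absent but O pairs exist, and 0 when both are
absent. Counting uses a sorted-array window search (O(n log n)) proven
equivalent to the all-pairs oracle in tests. Input peak lists are
deduplicated within 1 µDa so duplicated lists do not double pair counts.

**Bin QC and dereplication.** Quality filtering is strict: redundancy
< 1.1 % *and* contamination < 5 %, boundary values excluded. ANI between
bins is estimated from the Jaccard similarity J of canonical k-mer sets
(lexicographic minimum of forward and reverse-complement encodings, so
strandedness cannot change the estimate; k = 21 by default, odd so no
k-mer is its own reverse complement) through the Mash distance identity
ANI = 1 + (1/k) ln(2J/(1+J)), clamped to [0, 1]; disjoint k-mer sets are
flagged "no overlap" rather than given a fake distance. A k-mer estimator
is used because dereplication only compares ANI against a 0.99 threshold,
a regime where the Mash relation is accurate — validated by the planted
1 %-divergence recovery experiment. Bins with ANI ≥ 0.99 (inclusive) form
graph components; a component containing a same-station near-identical
pair is flagged merge-candidate wholesale (coassembly is out of scope),
otherwise the bin maximizing Q = completeness − 5 · contamination is
retained (ties: larger assembly, then lexicographic id) and the rest are
discarded naming it. The 5× contamination weight follows common
dereplication practice (dRep's default) and is configurable; a combined
score was chosen over lexicographic comparison because "more complete and
less contaminated" is otherwise not a total order. Decisions partition the
input and are independent of input order.

## The synthetic-data generator

The generators emulate the *structure* of the real inputs, not their
biology; they exist so every stage can be tested by parameter recovery.

- **Pangenomes**: per-(genome, family) copy counts are negative-binomial
  (dispersion 5) around a background mean of 2 copies, with planted
  (subgroup, family) expansions at an elevated mean — over-dispersion
  mimics real paralog-count variance. Default study conditions: 5
  subgroups × 20 genomes, 300 families, planted expansions at 10× the
  background. Subgroups occupy stacked depth bands (geometric spacing,
  10–6000 m). Single-copy marker families are planted at exactly one copy
  per genome. Totals per genome emerge as the sum of family counts.
- **Communities**: per-subgroup relative abundance follows a Gaussian
  niche curve in depth (center, width, peak) — the simplest unimodal shape
  matching observed depth peaks. Reads are multinomially allocated to
  genomes (niche weight split evenly within the subgroup) with the
  leftover mass unaligned, so aligned bases never exceed sample bases.
  Alignment identities are clipped normal. Gene catalogs are drawn
  genome-first, then family within genome, and tagged with the taxon.
- **Peak lists**: base formulas seed carbon ladders (spacing 12 Da)
  providing C pairs; a depth-dependent fraction of ladder peaks gains an
  oxidation partner at +15.994915 Da. Oxidation events are planted
  *deterministically* — the first ⌊p(depth)·n⌋ candidates of a seed-fixed
  ordering — so the truth O:C ratio is monotone whenever p(depth) is,
  making the qualitative depth trend exact in the truth record while the
  measured counts still face noise peaks and accidental coincidences.
- **Sequence pairs**: i.i.d. substitutions at a stated rate, every
  substitution guaranteed to change the base, realized counts recorded.
- **Depth-trend catalogs**: per-sample normalized abundance
  intercept + slope·depth + Gaussian noise, truncated at zero and rounded
  onto a 2000-gene single-copy denominator; defaults (slope 5·10⁻⁵ per m,
  noise sd 0.028) put the generating-model population r at ≈ 0.90 over the
  50–4000 m grid, the regime the depth-correlation recovery experiments
  target.

What the generators do **not** emulate: sequencing error and read-level
artifacts, assembly/binning chimerism, phylogenetic correlation among
genomes, compositionality of real annotation pipelines, isotopologue
patterns, or instrument drift. Passing recovery tests therefore
demonstrates the estimators are correct and well-calibrated under the
stated generative assumptions — not that real data meet those assumptions.

## Numerical choices and degenerate inputs

- All randomness flows from one integer seed through named, crc32-keyed
  child generators, so artifacts regenerate independently and runs are
  byte-identical.
- Z-scores of constant rows are 0; correlations of constant vectors are
  missing; a single-genome matrix is an error for Z-scoring (sample sd
  undefined), fewer than three genomes for correlation.
- Pearson p-values come from `scipy.stats.pearsonr`; agreement with an
  explicit two-pass covariance oracle is asserted to 1e-12.
- Mass tolerance scales with the heavier peak; translation invariance
  holds to < 1 ppm effect and is asserted at 5 ppm with shifts ≤ 100 Da.
- ANI values are clamped to [0, 1]; J = 0 short-circuits before the
  logarithm.
- Thresholds: identity and ANI cutoffs and the 1 % sample fraction are
  inclusive (≥); the QC thresholds are exclusive (<), as "less than"
  phrasing dictates.

## Validation problem sizes

The recovery experiments in `cnp.validation` (shared by the acceptance
tests and `scripts/acceptance.py`) run at the generators' study
conditions: 50 pangenome replicates of 5 × 20 genomes with 300 families;
20 depth-trend seeds at n = 100 plus a 1000-replicate null at n = 50; 50
community replicates of 10 samples × 5000 reads; 200 random mass-difference
instances of up to 500 peaks; 50 sequence pairs of 1 Mb at 1 % divergence.

## Known limitations

- The expansion score is a marginal mean ratio; it does not model
  phylogenetic non-independence of genomes within subgroups.
- The k-mer ANI estimator loses accuracy below ~90 % identity; it is fit
  for thresholding near 0.99, not for distance-matrix phylogenetics.
- Mass-difference counting is per sample; cross-sample (pooled) pair
  counting is not implemented.
- Merge candidates are flagged, never merged; coassembly requires an
  external assembler.
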