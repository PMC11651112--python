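# Methods

This note documents the statistical model behind each analysis, the
defaults and why they were chosen, the numerical edge cases, and what the
synthetic-data validation does and does not establish.

## Incidence aggregation

A strain is a CRISPR carrier when its best array reaches evidence level 4,
the highest confidence tier of CRISPRCasFinder-style annotation
(`min_evidence` is configurable down to 1). Species incidence is the carrier
proportion among sequenced strains; genus incidence is the **unweighted**
mean of species incidences, so a heavily resequenced species (e.g. a model
organism with hundreds of genomes) cannot dominate its genus. Strains with
an unknown evidence level count as non-carriers but stay in the denominator.
Taxon labels are matched case-sensitively after whitespace stripping; no
fuzzy matching is attempted, because silent label coercion is a worse
failure mode than an explicit join error. Reconciling taxa present in the
annotation source but absent from a community table (or vice versa) is left
to the consumer: the analyses simply drop genera without an incidence
annotation rather than imputing one.

## Read-based CRISPR load

The load of a sample is `matched_reads / total_reads`, where a read matches
if any database sequence occurs in it as an exact contiguous substring.
The database is the deduplicated set of direct repeats plus every reverse
complement, which makes matching strand-symmetric by construction. Each
read counts at most once. The denominator is the total read count of the
FASTQ before any quality filtering. Repeats shorter than 18 bp are rejected
(configurable constant): exact substring matching makes short motifs
spuriously frequent, and real direct repeats are ~21–48 bp.

### Repeat clustering

Greedy incremental clustering in the cd-hit style: sequences sorted by
length descending (ties lexicographic); each sequence joins the first
cluster whose representative it matches at ≥ 80% identity (inclusive
threshold — for ~30-bp repeats the boundary corresponds to about 6 bp of
difference), else founds a new cluster. Pairwise identity is the number of
identical positions in the optimal global alignment (match +1, mismatch −1,
gap open −5, gap extend −2) divided by the length of the shorter sequence.
The stiff gap penalty matters: with a lenient linear gap cost, shifted
alignments of short repeats harvest spurious matches and substitution-only
pairs no longer resolve to 1 − hamming/length, which is the natural reading
of an identity threshold on repeats of similar length. The word size
(default 5) acts purely as a k-mer prefilter — pairs sharing no 5-mer are
assumed to fall below threshold and are not aligned. This can occasionally
skip a true boundary-identity pair whose differences are spread every ~5 bp;
at the default threshold this is the same approximation the short-word
screening of the original tool family makes.

Cluster prevalence is the fraction of samples containing at least one
member (either strand); clusters with prevalence **strictly greater** than
0.5 are excluded in the filtered load, which is recounted against a
database rebuilt from the surviving clusters' members. A read matching both
a prevalent and a surviving repeat therefore still counts — it maps to a
surviving repeat. The filtered load can never exceed the unfiltered load,
and lowering the cutoff never increases it.

## Density analyses

The split-half statistic restricts a sample to genera with positive count
and known incidence, sorts them ascending by abundance (ties broken by
taxon label for determinism), puts the first ⌈n/2⌉ genera in the rare half
(odd n favors the rare half), and compares the abundance-weighted mean
incidences Σa·I/Σa of the halves. Because both halves and both weightings
are invariant to a positive rescaling of the column, relative and absolute
abundance give identical results — so missing cell counts do not change
this analysis.

The binned-median curve pools one (abundance, incidence) observation per
(genus, sample) with positive abundance, sorts ascending by abundance (ties
by incidence then input order), takes consecutive bins of 500 observations,
and reports each bin's median abundance and median incidence. A trailing
incomplete bin is dropped rather than reported at reduced support. With
cell counts, abundance is relative abundance × cells per unit volume.

Prevalent-genus removal retains a genus iff its presence fraction is
≤ 0.75 (strict `>` removed, matching "more than 75%"); the filter is
idempotent. The MAG contrast uses a two-sided Mann–Whitney rank-sum test
(exact for small untied samples via scipy) with direction = sign of the
median difference (without − with); the underlying claim is about ranks,
not means, so a rank test is the conservative choice where no test is
otherwise dictated.

## Diversity analyses

Rarefaction is a single multivariate-hypergeometric draw to exactly 2,000
reads per sample (one draw with a recorded seed, not an average over
draws); samples below depth are excluded with a logged reason. Each sample
gets an independent child stream of the run seed, so exclusion of one
sample cannot shift another's draw. Shannon's H uses the natural log;
zero-count genera contribute nothing; the all-zero vector is an error.

Per-sample CRISPR incidence is the abundance-weighted mean of genus
incidences over annotated genera (unweighted mean available), consistent
with the abundance weighting used in the density analyses. The
incidence–diversity association is ordinary least squares of incidence on
H, with r² the squared Pearson correlation and a two-sided p-value for the
slope; zero variance in either variable is an error rather than a NaN.

Alpha-matched pairing forms all unordered sample pairs with
|H_i − H_j| / max(H_i, H_j) ≤ 0.05. The degenerate pair H_i = H_j = 0 is
*paired* (the difference is zero even though the relative criterion is
0/0); tolerance 0 reduces to exact equality. Bray–Curtis is computed on the
same rarefied counts used for Shannon, for comparability. The within-pair
|Δincidence| vs Bray–Curtis regression reuses the OLS machinery; pairs
share samples and are not independent, so that p-value is descriptive
only. p-values below 1e-300 are printed as 0.

## Synthetic communities

The community generator emulates the statistical structure of genus-level
16S survey tables: genus mean log-abundances are normal with sd 1.5
(log-normal abundances, heavy-tailed); each sample jitters every genus
log-mean by an independent N(0, 2²) perturbation before a multinomial draw
of 10,000 reads. The large per-sample jitter reflects how strongly genus
abundances vary between, say, ocean stations, and keeps samples close to
exchangeable replicates under a null density effect. Cell counts are
log-normal around 5×10⁵ per unit volume (flow-cytometry scale). Each genus
receives 1–10 strains split over 1–3 species, and carriage is planted at
the strain level — probability expit(α − β·z + ε), with z the standardized
log mean abundance, β the density effect (default 2), ε ~ N(0, 0.5²) — so
the incidence module is exercised end to end rather than handed genus
incidences directly.

The read simulator draws i.i.d. background bases at a chosen GC content
and, with probability λ per read, overwrites a window with a pool repeat
(random member, strand, offset). At 100-bp reads and ≥24-bp repeats the
background false-match probability is ≪ 1e-3, so the measured load is an
almost-unbiased binomial estimate of λ. The diversity gradient sweeps a
symmetric Dirichlet concentration geometrically from 0.1 to 30 and couples
expected incidence to the realized Shannon index as
clip(0.1 + γ·H + N(0, 0.05²), 0, 1), γ default 0.1 so incidence stays
inside the unit interval across the whole H range.

What the generators deliberately omit: phylogenetic correlation between
genera, sequencing error and chimeras, genome-derived read composition,
real repeat phylogenetics (pool repeats are uniform random), and spatial or
geographic structure. Passing the recovery tests therefore shows the
estimators are correct and well-calibrated under the stated sampling model,
not that real data meet that model.

## Validation scales and reproducibility

The end-to-end checks run at desk scale, chosen to keep the binomial /
OLS error bars far smaller than the planted effects: 100 samples × 200
genera for density recovery (null split-half win fraction calibrated to
0.5 ± 0.15 across seeds before freezing), 50,000 reads per sample for load
recovery (3 binomial SE), 100 replicates for slope-sign and null-r²
frequencies, and n = 2,000 for the planted-R² construction. All generators
are seed-deterministic; CLI runs write a manifest (parameters, seed, input
SHA-256, version, no timestamps) and are byte-identical on rerun.

## Known limitations

Exact substring matching does not tolerate sequencing errors in the repeat,
so measured loads underestimate true CRISPR activity at realistic error
rates; the greedy clustering is order-dependent by design (as in the tool
family it mirrors) and does not guarantee that members of *different*
clusters are below threshold; genus incidence from reference databases is
environment-independent by construction; and the beta-diversity regression
inherits the non-independence of overlapping pairs.
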