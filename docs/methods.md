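# Methods

This note documents the statistical procedures implemented by `litscape`,
the assumptions behind them, the synthetic data used to validate them, and
the numerical and design choices a maintainer would want recorded.

## Unit of analysis and classification

The unit is one abstract-bearing publication record: an opaque id, a
calendar year, raw affiliation strings, and the gene symbols an upstream
named-entity-recognition step found in the abstract.  All counting uses the
*deduplicated* per-publication gene set; a publication is classified as
genetics research iff that set is non-empty.  Raw mention counting is
exposed (`gene_publication_counts(unit="mentions")`) but is not the default,
because every network and enrichment construction downstream is
publication-based.  Records without gene annotations are legitimate
non-genetics records; only records whose year cannot be parsed are dropped
(and counted in provenance).

## Affiliation geocoding

Affiliations are resolved by text matching, not by an external geocoding
service.  Each string is split on ";" into subgroups and on "," into
tokens; tokens are tried right-to-left, cleaned of e-mail fragments,
digits/postal codes and punctuation, and matched case-insensitively against
a gazetteer (countries, aliases such as "UK"→"United Kingdom", US
states/abbreviations→"United States", and focal-country cities).  The
last token has priority — when it matches, earlier tokens are never
consulted; the right-to-left fallback exists so that trailing e-mail
addresses or postal codes do not turn an otherwise well-formed
", City, Country" affiliation into a miss.  An affiliation carrying no
place name at all (e.g. a bare institution) yields no match; a record is
kept if *any* of its affiliations resolves, and dropped (with provenance
accounting) only when none does.  US states are the only sub-national
entities mapped; no analogous province lists exist for other countries.
The gazetteer ships as a versioned plain-text TSV and can be replaced by
the user.

## Collaboration matrices

Country and city matrices are symmetric nonnegative-integer matrices whose
off-diagonal entry (i, j) counts publications containing both entities; a
publication with three or more entities increments every unordered pair
once (no weighting by author counts).  The diagonal stores only
*self-collaborations* — publications whose entity set is a singleton —
because that is the quantity the collaboration analyses actually report;
per-entity publication totals are kept as a separate vector rather than on
the diagonal, since for multi-entity papers no single diagonal convention
makes row sums equal totals.  Merging sub-threshold countries into
"Others" (default: fewer than 1,000 publications) sums rows and columns
element-wise, which preserves symmetry and the grand total of entries.
Percentages (e.g. self-collaboration rates) are kept at full precision
internally and rounded half-even only at report time.

## Gene–gene literature networks

A[i, j] counts publications jointly mentioning genes i and j (diagonal:
per-gene publication totals, excluded from thresholding).  The unweighted
graph keeps an edge where A[i, j] > Θ, *strictly*; a pair seen in exactly
Θ publications has no edge.  The threshold's conservativeness is
quantified by the exceedance probability: the fraction of *realized* pairs
(count ≥ 1) whose count exceeds Θ.  Realized pairs are used as the
denominator because the frequency distribution estimated from literature
is observable only on pairs that co-occur at all; with all C(G, 2)
possible pairs the probability would be smaller still.  Communities
default to connected components of the thresholded graph — on real corpora
the reported community structure (including two-gene isolates) is exactly
the component structure — with a greedy-modularity alternative pluggable
for denser graphs.

## Exact enrichment test

For a threshold γ, each gene studied worldwide is labelled HS-yes iff its
worldwide publication count strictly exceeds γ, and City-in iff it appears
in at least one of the city's publications.  Under the null that
highly-studied status is independent of the city, the City-in count x
among the n₁₊ HS-yes genes follows the hypergeometric law

    P(k) = C(n₊₁, k) · C(n − n₊₁, n₁₊ − k) / C(n, n₁₊),

and the reported p-value is the strict upper tail p = P(K > x), summed
from x + 1 to min(n₁₊, n₊₁).  Two numerical/definitional choices:

* The observed x is **excluded** from the tail.  This is the statistic
  the pipeline standardizes on; the conventional one-sided exact test (which
  includes x and is the guaranteed-level version) is available via
  `include_observed=True`.  The strict tail is anti-conservative where the
  support is small — e.g. with only 3 HS-yes genes its realized level can
  be ~1.5× nominal — which matters for how sweep results are read (below).
* P(k) is computed in log-space via log-gamma and combined with
  `logsumexp`, so margins in the thousands (a 7,519-gene worldwide list)
  neither overflow nor lose the tail.

Degenerate tables — any zero margin, i.e. no gene selected as highly
studied, every gene selected, or an empty city — return p = 1 by
convention: nothing can be enriched against an empty or exhaustive
reference.  The sweep repeats the test over a user-supplied γ list
(never hard-coded) with Bonferroni control at α/m, m the list length.
A city is *detected as enriched* when every interior threshold (0 <
n₁₊ < n) is significant; requiring robustness across the whole sweep is
the procedure's own decision rule and keeps the family-wise false
detection rate of the strict-exclusion tail at zero in our null
simulations, whereas flagging on any single interior γ would inherit the
tail's anti-conservativeness (~10% family-wise in the same simulations).

Correctness is established against two independent routes: full subset
enumeration for every margin combination with n ≤ 12 (agreement to
1e-12), and `scipy.stats.hypergeom.sf` on random large margins.

## Trend regressions

For an entity (one country, or all countries pooled) the yearly percentage
of genetics research is 100 × genetics/total over the publications
containing that entity; years without publications are omitted, not
imputed as zero.  Years fall into three fixed intervals, A: 1987–1996,
B: 1997–2006, C: 2007–2018.  For an interval pair the yearly percentages
are regressed on a 0/1 interval indicator (not on calendar year): the OLS
slope then equals the difference of interval means, and the two-sided
t-test of zero slope is the trend test.  Interval-level shifts in
genetics-research percentage are typically on the order of 15–30 points
per decade — far too large to be per-year slopes — which is why the
indicator design is the default rather than a within-interval linear
trend.  Each year is one unweighted point; at least two yearly points per
interval are required.  Multiple entities are corrected with Bonferroni
at α/m.

## City clustering

M[i, j] counts publications mentioning top-gene i with an author in city
j (a multi-city publication counts once per city).  Cities — the column
vectors of M over the gene axis — are clustered agglomeratively with
Ward's minimum-variance criterion on Euclidean distances (the classical
Lance–Williams update on Euclidean input, i.e. the Ward.D2-equivalent
variant), with **no standardization** of the raw counts.  Clustering is
deterministic given the matrix and invariant to city input order up to
leaf order.  The number of clusters is read off the dendrogram by the
user, not chosen automatically.  Per-gene city proportions are the
row-normalized matrix; zero rows are excluded with a warning since their
proportions are undefined.  Dendrograms export as Newick with branch
lengths given by merge-height differences, so every leaf's root distance
equals the root merge height.

## Synthetic corpus generator

The generator emulates the gross statistical structure of a ~100k-record
disease literature corpus at a scaled size, with defaults chosen once on
realism grounds:

* `n_pubs = 5000` records over 1987–2018 (scaled from ~107,500);
* `n_genes = 300` with Zipf exponent 1.1 — this keeps the corpus's ~14
  publications-per-gene ratio and puts the top gene in roughly a fifth of
  genetics abstracts, matching the skew of real gene-mention counts;
* `genes_per_pub = 5` (shifted Poisson, ≥ 1): entity recognition that
  expands gene families (a single abstract can be annotated with ten
  MAPK-family symbols) makes multi-gene abstracts the norm;
* per-interval genetics fractions A: 0.40, B: 0.58, C: 0.57 — a ~18-point
  rise between the early intervals and a plateau after, the pattern the
  trend module is designed to detect;
* one dominant country (United States, 44% share) with a long tail of 31
  others, 20% international papers (extra countries drawn without
  replacement, geometric tail beyond two), and Finland as the focal
  country with city weights proportional to real per-city publication
  counts (Helsinki 180 : Tampere 165 : Turku 116 : Oulu 64 : Kuopio 58 :
  Espoo 12 : Jyväskylä 1).

Affiliations are synthesized as "Department, Institute, City, Country" so
geocoding runs on realistic-shaped strings; an optional fraction of
records gets no place name at all, to exercise the drop-with-provenance
path.  All randomness flows from one seed split into named per-stage
streams (years, genetics status, gene counts, gene choice, countries,
cities, unlocatable), so adding a stage never perturbs earlier draws and
a fixed seed yields a byte-identical corpus.  `plant_gene_pair` inserts a
gene pair into exactly n chosen genetics records (and removes the pair
elsewhere), making thresholding tests exact.

What the generator does **not** emulate: natural-language abstracts (only
structured annotations), messy real-world affiliation dialects beyond the
canonical comma/semicolon form, correlation between a paper's country and
its genes (except via the optional planted-enrichment mechanism), author
counts, and within-year publication growth.  Passing tests therefore
demonstrate the correctness of the computational procedures and their
operating characteristics under the planted model — not robustness to
free-text affiliation noise or NER errors, which are upstream concerns.

## Validation scales and operating characteristics

Brute-force oracles (pair enumeration, subset enumeration, full sorting,
pooled t-tests) back every counting and testing operation at small scale.
Simulation-based checks use: 200 replicates for enrichment detection
(planted cities sample 60 genes with weight ∝ count², emulating the
strong top-rank overlap seen in real city gene sets; null cities sample
uniformly), and 200/1000 replicates for the interval-step power and null
calibration at ~10 publications per year over two 10-year intervals.  At
that yearly scale the indicator-coded slope test — equivalent to a pooled
two-sample t-test — has noncentrality ≈ 2.5 for an 18-point step
(yearly-percentage SD ≈ 15.5 points), hence power ≈ 0.65–0.70; its null
level is accurate (≈ 0.049).  Power reaches ~0.93 at 20 publications per
year, so detection of decade-scale shifts is comfortable at real corpus
sizes and marginal at the 10-per-year scale.

## Known limitations

* Geocoding recall on real affiliations depends entirely on gazetteer
  coverage; the shipped gazetteer covers countries, US states and Finnish
  cities only.
* The strict-exclusion exact tail is not a guaranteed-level test; use
  `include_observed=True` when level control per threshold matters.
* Connected components as the community default is an inference from the
  reported community structure, not a stated algorithm; modularity-based
  detection is available but will differ on dense graphs.
* The regression design (indicator coding on yearly points) is likewise a
  reconstruction from reported slope magnitudes; a per-year linear trend
  within intervals is deliberately out of scope.
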