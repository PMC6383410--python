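# litscape

Bibliometric network analysis of disease-genetics literature, built around
the study design used for large cancer corpora: tens of thousands of
publication abstracts annotated with gene mentions and author affiliations,
mined for who studies what, where, and with whom.

`litscape` is for computational biologists and bibliometricians who have a
corpus of annotated publication records (publication id, year, raw
affiliation strings, gene symbols found in the abstract) and want the full
downstream analysis:

* **Geocoding by text matching** — each affiliation's comma tokens are
  matched right-to-left against a gazetteer of countries, country aliases
  and US states (a bare "NY" resolves to United States); records that
  cannot be located are dropped with provenance accounting.
* **Collaboration networks** — symmetric country x country (and, within a
  focal country, city x city) matrices where entry (i, j) counts joint
  publications; the diagonal counts *self-collaborations* (papers whose
  authors all resolve to one country/city); small countries can be merged
  into an "Others" group and top-k pairs exported as (source, target,
  value) chord tables.
* **Gene–gene literature networks** — A[i, j] = number of publications
  jointly mentioning genes i and j; an edge is drawn where A[i, j] > Θ
  (strict, default Θ = 10) and communities default to connected
  components of the thresholded graph.
* **Exact enrichment of city gene sets** — each gene studied worldwide is
  labelled HS-yes/no (worldwide count strictly above a threshold γ) and
  City-in/out; the 2×2 table is tested with the exact hypergeometric tail

      P(k) = C(n₊₁, k) · C(n − n₊₁, n₁₊ − k) / C(n, n₁₊),
      p = P(K > x) = Σ_{k = x+1}^{min(n₁₊, n₊₁)} P(k),

  repeated over a sweep of γ thresholds with Bonferroni control at α/m.
* **Trend regressions** — per-country yearly "percentage of genetics
  research" (100 × genetics papers / all papers), with OLS of the yearly
  percentages on a 0/1 interval indicator for the interval pairs
  (1987–1996 vs 1997–2006) and (1997–2006 vs 2007–2018); the slope equals
  the difference of interval means and its t-test is the trend test.
* **City clustering** — cities as count vectors over the top genes,
  Ward/Euclidean agglomerative clustering plus row-normalized per-gene
  city proportions.
* **Synthetic corpora with planted truth** — Zipf gene popularity, a
  dominant country with a long tail, interval-wise genetics fractions and
  focal-country city assignment, so every stage is testable offline.

## Worked example

Generate a 5,000-record synthetic corpus and build its gene network:

```sh
$ litscape simulate --seed 42 --out demo.jsonl
wrote 5000 records to demo.jsonl
$ litscape genenet --corpus demo.jsonl --theta 10 --out-dir .
440 edges, 1 communities at theta=10
```

The same corpus from Python:

```python
>>> from litscape import (read_corpus, gene_publication_counts, top_genes,
...                       classify_genetics, genetics_percentage)
>>> corpus = read_corpus("demo.jsonl")
>>> counts = gene_publication_counts(corpus)
>>> top_genes(counts, 5)
['KLK3', 'NPEPPS', 'AR', 'KLK2', 'TMPRSS2']
>>> [int(counts[g]) for g in top_genes(counts, 5)]
[1709, 1095, 736, 575, 462]
>>> n_genetics = sum(classify_genetics(r) for r in corpus.records)
>>> round(genetics_percentage(n_genetics, len(corpus)), 2)
51.82
```

`KLK3` leads with 1,709 of 5,000 publications because gene popularity is
Zipf-distributed with the well-known prostate-cancer genes planted at the
top ranks; 51.82% of records mention at least one gene, the corpus-wide
average of the planted per-interval genetics fractions.  The full pipeline
(`litscape run --config config.yaml`) chains geocoding, classification,
networks, enrichment, trends and clustering, and writes every table, edge
list, dendrogram and a provenance log to one output directory,
byte-identically for a fixed seed.

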