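"""End-to-end orchestration of the literature-landscape analysis.

``run`` sequences ingest (or synthesis) -> geographic extraction ->
genetics classification -> collaboration and gene networks -> enrichment
sweep -> trend regressions -> city clustering, writing every table and
graph export plus a provenance log into one output directory.  Runs are
idempotent: a fixed corpus (or synthetic spec + seed) and configuration
produce byte-identical output bundles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import collab, cluster, enrichment, genenet, geo, synthetic, trends
from .corpus import (Corpus, gene_publication_counts, first_mention, read_corpus,
                     top_genes, write_corpus)

__all__ = ["PipelineConfig", "PipelineError", "run", "load_config"]

log = logging.getLogger("litscape")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""


@dataclass
class PipelineConfig:
    corpus_path: str | None = None
    synthetic: dict | None = None            # SyntheticSpec field overrides
    gazetteer_path: str | None = None
    focal_country: str = "Finland"
    theta: int = 10
    gammas: list[int] = field(default_factory=lambda:
                              [5000, 2000, 1000, 500, 200, 100, 50, 20, 10, 0])
    alpha: float = 0.05
    intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(trends.DEFAULT_INTERVALS))
    top_k: int = 19
    others_min: int = 1000
    out_dir: str = "litscape_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.corpus_path is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of corpus_path / synthetic")
        if self.corpus_path is not None and not Path(self.corpus_path).exists():
            raise ValueError(f"corpus file not found: {self.corpus_path}")
        if self.gazetteer_path is not None and not Path(self.gazetteer_path).exists():
            raise ValueError(f"gazetteer file not found: {self.gazetteer_path}")
        if self.theta < 0 or self.top_k < 1 or self.others_min < 0:
            raise ValueError("theta/top_k/others_min out of range")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "intervals" in raw:
        raw["intervals"] = {k: tuple(v) for k, v in raw["intervals"].items()}
    return PipelineConfig(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run(config: PipelineConfig) -> dict[str, str]:
    """Execute the full pipeline; returns a manifest of artifact paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(key: str, path: Path) -> None:
        manifest[key] = str(path)

    # --- ingest -----------------------------------------------------------
    @_stage("ingest")
    def ingest() -> Corpus:
        if config.synthetic is not None:
            spec = synthetic.SyntheticSpec(**{**config.synthetic, "seed": config.seed})
            corpus, truth = synthetic.generate(spec)
            write_corpus(corpus, out / "corpus.jsonl")
            truth.to_json(out / "ground_truth.json")
            emit("corpus", out / "corpus.jsonl")
            emit("ground_truth", out / "ground_truth.json")
            return corpus
        return read_corpus(config.corpus_path)

    corpus = ingest()

    # --- geographic extraction -------------------------------------------
    @_stage("geo")
    def geocode(c: Corpus) -> Corpus:
        gaz = (geo.load_gazetteer(config.gazetteer_path)
               if config.gazetteer_path else geo.default_gazetteer())
        geo.annotate_corpus(c, gaz, focal_country=config.focal_country)
        return geo.drop_unlocated(c)

    corpus = geocode(corpus)

    # --- classification & per-gene counts --------------------------------
    @_stage("classify")
    def classify(c: Corpus):
        if len(c) == 0:
            raise ValueError("corpus is empty after filtering; nothing to classify")
        counts = gene_publication_counts(c)
        counts.to_csv(out / "gene_counts.tsv", sep="\t")
        emit("gene_counts", out / "gene_counts.tsv")
        return counts

    world_counts = classify(corpus)
    top = top_genes(world_counts, min(config.top_k, len(world_counts)))

    @_stage("first_mentions")
    def mentions():
        rows = ["gene\tyear\tcountries"]
        for g in top:
            year, countries = first_mention(corpus, g)
            rows.append(f"{g}\t{year}\t{';'.join(sorted(countries))}")
        (out / "first_mentions.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
        emit("first_mentions", out / "first_mentions.tsv")

    mentions()

    # --- collaboration networks ------------------------------------------
    @_stage("networks")
    def networks():
        cm = collab.country_matrix(corpus)
        totals = collab.publication_totals(corpus, "country")
        grouped = collab.group_others(cm, totals, min_pubs=config.others_min)
        grouped.write_tsv(out / "country_matrix.tsv")
        emit("country_matrix", out / "country_matrix.tsv")
        chord = collab.chord_export(cm, k=min(10, len(cm.labels)), totals=totals)
        chord.to_csv(out / "country_chord.csv", index=False)
        emit("country_chord", out / "country_chord.csv")

        gm = genenet.gene_matrix(corpus)
        graph = genenet.threshold_graph(gm, theta=config.theta)
        genenet.export_graph(graph, out / "gene_network_edges.tsv", "edgelist")
        emit("gene_network", out / "gene_network_edges.tsv")
        comms = genenet.communities(graph)
        (out / "gene_communities.json").write_text(
            json.dumps([sorted(c) for c in comms], indent=2), encoding="utf-8")
        emit("gene_communities", out / "gene_communities.json")

        citym = collab.city_matrix(corpus, config.focal_country)
        citym.write_tsv(out / "city_matrix.tsv")
        emit("city_matrix", out / "city_matrix.tsv")

    networks()

    # --- enrichment sweep -------------------------------------------------
    @_stage("enrichment")
    def enrich():
        frames = []
        cities = collab.publication_totals(corpus, "city",
                                           focal_country=config.focal_country)
        for city in cities.sort_values(ascending=False).index[:3]:
            city_genes = set()
            for r in corpus.records:
                if r.cities and city in r.cities:
                    city_genes |= r.gene_set
            results = enrichment.sweep(world_counts, city_genes & set(world_counts.index),
                                       config.gammas, alpha=config.alpha)
            frame = enrichment.results_to_frame(results)
            frame.insert(0, "city", city)
            frames.append(frame)
        if frames:
            import pandas as pd
            pd.concat(frames).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            emit("enrichment", out / "enrichment.tsv")

    enrich()

    # --- trend regressions ------------------------------------------------
    @_stage("trends")
    def trend():
        totals = collab.publication_totals(corpus, "country")
        entities = [trends.ALL_COUNTRIES] + [
            c for c in totals.sort_values(ascending=False).index
            if totals[c] >= config.others_min]
        results = []
        for entity in entities:
            series = trends.build_series(corpus, entity, intervals=config.intervals)
            for pair in (("A", "B"), ("B", "C")):
                try:
                    results.append(trends.interval_regression(series, pair))
                except ValueError as exc:
                    log.warning("skipping %s %s: %s", entity, pair, exc)
        table = trends.regression_table(results)
        if len(table):
            flags = trends.bonferroni(table["p_value"].tolist(), alpha=config.alpha)
            table["significant"] = flags
        table.to_csv(out / "trends.tsv", sep="\t", index=False)
        emit("trends", out / "trends.tsv")

    trend()

    # --- city clustering --------------------------------------------------
    @_stage("clustering")
    def clustering():
        M = cluster.gene_city_matrix(corpus, top, config.focal_country)
        if len(M.cities) >= 2:
            dend = cluster.ward_cluster(M)
            cluster.to_newick(dend, out / "city_dendrogram.nwk")
            emit("city_dendrogram", out / "city_dendrogram.nwk")
        props = cluster.gene_city_proportions(M)
        props.to_csv(out / "gene_city_proportions.tsv", sep="\t",
                     index_label="gene", float_format="%.10g")
        emit("gene_city_proportions", out / "gene_city_proportions.tsv")

    clustering()

    # --- provenance -------------------------------------------------------
    (out / "provenance.json").write_text(
        json.dumps(corpus.provenance, indent=2, sort_keys=True), encoding="utf-8")
    emit("provenance", out / "provenance.json")
    (out / "manifest.json").write_text(
        json.dumps({k: Path(v).name for k, v in manifest.items()},
                   indent=2, sort_keys=True), encoding="utf-8")
    return manifest
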