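"""End-to-end orchestration: models → dedup → adjacency → families → matrix.

Shared by the command-line interface, the test suite, and the acceptance
script.  Hit production is pluggable: the built-in exact aligner, or
precomputed tabular files laid out as ``<tag>.self.tsv`` (self-comparison)
and ``<qtag>__<stag>.tsv`` (directed inter-genome hits) in a directory.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

from .clustering import AdjacencyPairs, GeneFamily, build_adjacency, greedy_cluster
from .errors import ConfigError, IntegrityError
from .io_formats import GeneModel, GenomeSet, HitRecord, read_fasta, read_hit_table
from .metagenome import MetagenomeMatrix, build_matrix, name_families
from .redundancy import DedupReport, dedup_genome, kept_models
from .similarity import (
    DEFAULT_PARAMS,
    DEFAULT_THRESHOLD,
    AlignmentParams,
    SimilarityThreshold,
    all_vs_all,
    cross_hits,
)

log = logging.getLogger("phyletic")


class HitSource(Protocol):
    def self_hits(self, tag: str, models: Sequence[GeneModel]) -> list[HitRecord]: ...

    def pair_hits(self, tag_a: str, models_a: Sequence[GeneModel],
                  tag_b: str, models_b: Sequence[GeneModel],
                  ) -> tuple[list[HitRecord], list[HitRecord]]: ...


class BuiltinHitSource:
    """Exact all-vs-all comparison with the built-in aligner."""

    def __init__(self, params: AlignmentParams = DEFAULT_PARAMS,
                 threshold: SimilarityThreshold = DEFAULT_THRESHOLD):
        self.params = params
        self.threshold = threshold

    def self_hits(self, tag, models):
        return all_vs_all(models, models, self.params, self.threshold)

    def pair_hits(self, tag_a, models_a, tag_b, models_b):
        return cross_hits(models_a, models_b, self.params, self.threshold)


class TabularHitSource:
    """Precomputed 12-column hit tables produced by an external search
    tool.  Missing files are a hard error: with externally computed hits
    the pipeline cannot tell an absent comparison from an empty one."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise ConfigError(f"hit-table directory not found: {self.directory}")

    def _read(self, filename: str) -> list[HitRecord]:
        path = self.directory / filename
        if not path.is_file():
            raise ConfigError(f"missing hit table {path}")
        return read_hit_table(path)

    def self_hits(self, tag, models):
        return self._read(f"{tag}.self.tsv")

    def pair_hits(self, tag_a, models_a, tag_b, models_b):
        return (self._read(f"{tag_a}__{tag_b}.tsv"),
                self._read(f"{tag_b}__{tag_a}.tsv"))


@dataclass
class PipelineResult:
    models: dict[str, list[GeneModel]]
    dedup: dict[str, DedupReport]
    kept: dict[str, list[GeneModel]]
    adjacency: AdjacencyPairs
    families: list[GeneFamily]
    matrix: MetagenomeMatrix


def load_genomes(genome_set: GenomeSet, *, permissive: bool = False,
                 ) -> dict[str, list[GeneModel]]:
    models: dict[str, list[GeneModel]] = {}
    for entry in genome_set.entries:
        if entry.fasta is None:
            raise ConfigError(f"genome {entry.tag}: no FASTA path configured")
        models[entry.tag] = read_fasta(entry.fasta, entry.tag, permissive=permissive)
    return models


def run_pipeline(models_by_genome: Mapping[str, Sequence[GeneModel]],
                 genome_set: GenomeSet,
                 threshold: SimilarityThreshold = DEFAULT_THRESHOLD,
                 params: AlignmentParams = DEFAULT_PARAMS,
                 require_reciprocal: bool = True,
                 source: HitSource | None = None) -> PipelineResult:
    """Run the full workflow in memory.

    Genomes are processed in ascending tag order.  Gene-model IDs must be
    unique across the whole run (family names are IDs).
    """
    tags = genome_set.tags
    missing = set(tags) - set(models_by_genome)
    if missing:
        raise ConfigError(f"no models supplied for genomes {sorted(missing)}")
    if source is None:
        source = BuiltinHitSource(params, threshold)

    seen: dict[str, str] = {}
    for tag in tags:
        for m in models_by_genome[tag]:
            if m.id in seen:
                raise IntegrityError(
                    f"gene-model ID {m.id} appears in both {seen[m.id]} and {tag}")
            seen[m.id] = tag

    dedup: dict[str, DedupReport] = {}
    kept: dict[str, list[GeneModel]] = {}
    for tag in tags:
        models = list(models_by_genome[tag])
        report = dedup_genome(models, source.self_hits(tag, models), threshold)
        dedup[tag] = report
        kept[tag] = kept_models(models, report)
        log.info("dedup %s: %d models, %d kept, %d removed",
                 tag, len(models), len(kept[tag]), len(report.removed))

    nodes = {m.id: tag for tag in tags for m in kept[tag]}
    hit_lists = []
    for tag_a, tag_b in itertools.combinations(tags, 2):
        ab, ba = source.pair_hits(tag_a, kept[tag_a], tag_b, kept[tag_b])
        hit_lists.append(ab)
        hit_lists.append(ba)
        log.info("compare %s vs %s: %d + %d significant hits",
                 tag_a, tag_b, len(ab), len(ba))
    adjacency = build_adjacency(itertools.chain.from_iterable(hit_lists),
                                nodes, threshold, require_reciprocal)
    families = name_families(greedy_cluster(adjacency), tags)
    matrix = build_matrix(families, genome_set)
    log.info("clustered %d retained models into %d families (%d edges)",
             len(nodes), len(families), len(adjacency.edges))
    return PipelineResult(
        models={tag: list(models_by_genome[tag]) for tag in tags},
        dedup=dedup, kept=kept, adjacency=adjacency,
        families=families, matrix=matrix,
    )
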