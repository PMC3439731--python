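"""Synthetic multi-genome protein sets with planted family structure.

The generator emulates the raw material of a gain/loss analysis: sets of
ab initio predicted protein models per genome, containing

* families planted with chosen phyletic patterns (universal, unique to a
  genome, exclusive to a pair, or arbitrary tag subsets),
* sequence divergence between family members (independent per-site
  substitutions of each member away from a common ancestral sequence), and
* within-genome redundancy: truncated duplicate copies (30–70% prefix or
  suffix) of existing models, mimicking the fragmented gene models of
  short-read draft genomes, which the dedup stage must remove.

Everything is reproducible from the seed, and the planted ground truth
(presence/absence matrix, family memberships, fragment manifest) is
returned alongside the sequences so every pipeline stage can be checked
end to end.

Substitutions are uniform over the 19 alternative residues; no rate
matrix, and no indels beyond the fragment mechanism.  The pipeline only
consumes similarity significance, not evolutionary realism.  One
consequence worth knowing: two copies independently mutated from an
ancestor at per-site rate r still match at a fraction (1-r)^2 + r^2/19 of
sites, which is bounded below by ~26% as r approaches 0.5 — uniform
mutation cannot push homologs below the similarity twilight zone at
typical protein lengths, so very high sub_rate values weaken but do not
abolish detectability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PhyleticError
from .io_formats import GeneModel, GenomeEntry, GenomeSet, write_fasta, write_matrix
from .metagenome import MetagenomeMatrix

# The 12 genome tags of the reference study setup, ascending.
DEFAULT_TAGS = ("am", "ar", "br", "ca", "da", "ho", "lo", "mo", "ne", "sa", "tr", "ur")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(_AA.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic fixture.

    Defaults describe the standard test scenario: 12 genomes, 50 universal
    families, 20 genome-unique families each, 5 families exclusive to the
    ar/tr pair, 5% per-copy substitution rate, 10% fragment injection.
    Family lengths are drawn from a normal(mean_len, len_sd) clipped at
    ``min_len`` = 60 residues so that every injected fragment (at least 30
    residues, the realistic floor for a predicted model fragment) stays
    unambiguously detectable against its parent.
    """

    tags: tuple[str, ...] = DEFAULT_TAGS
    n_universal: int = 50
    n_unique_per_genome: int = 20
    n_pair_exclusive_per_pair: int = 5
    exclusive_pairs: tuple[tuple[str, str], ...] = (("ar", "tr"),)
    extra_patterns: tuple[tuple[tuple[str, ...], int], ...] = ()
    mean_len: float = 250.0
    len_sd: float = 50.0
    min_len: int = 60
    sub_rate: float = 0.05
    fragment_rate: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if len(set(self.tags)) != len(self.tags) or not self.tags:
            raise PhyleticError("tags must be non-empty and unique")
        for count in (self.n_universal, self.n_unique_per_genome,
                      self.n_pair_exclusive_per_pair):
            if count < 0:
                raise PhyleticError("pattern counts must be >= 0")
        if not (0.0 <= self.sub_rate < 0.5):
            raise PhyleticError("sub_rate must be in [0, 0.5)")
        if not (0.0 <= self.fragment_rate <= 1.0):
            raise PhyleticError("fragment_rate must be in [0, 1]")
        if self.mean_len < 30:
            raise PhyleticError("mean_len must be >= 30 residues")
        tag_set = set(self.tags)
        for a, b in self.exclusive_pairs:
            if a == b or a not in tag_set or b not in tag_set:
                raise PhyleticError(f"bad exclusive pair ({a}, {b})")
        for subset, count in self.extra_patterns:
            if count < 0 or not subset or not set(subset) <= tag_set:
                raise PhyleticError(f"bad extra pattern {subset}")

    def patterns(self) -> list[tuple[str, ...]]:
        """The planted phyletic patterns, one per family, in a fixed
        deterministic order (universal, unique per tag, pair-exclusive,
        extras)."""
        ordered_tags = tuple(sorted(self.tags))
        pats: list[tuple[str, ...]] = []
        pats += [ordered_tags] * self.n_universal
        for tag in ordered_tags:
            pats += [(tag,)] * self.n_unique_per_genome
        for a, b in self.exclusive_pairs:
            pats += [tuple(sorted((a, b)))] * self.n_pair_exclusive_per_pair
        for subset, count in self.extra_patterns:
            pats += [tuple(sorted(set(subset)))] * count
        return pats


@dataclass
class GroundTruth:
    """What the generator planted: the presence matrix the pipeline should
    recover, the family memberships behind it, and the injected redundant
    fragments mapped to their parent models."""

    presence: pd.DataFrame
    memberships: dict[str, tuple[str, ...]]
    fragments: dict[str, str]

    def matrix(self) -> MetagenomeMatrix:
        return MetagenomeMatrix(presence=self.presence.copy())


def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    seq = ancestor.copy()
    if rate > 0:
        hit = rng.random(seq.shape[0]) < rate
        n_hit = int(hit.sum())
        if n_hit:
            # uniform over the 19 alternative residues
            seq[hit] = (seq[hit] + rng.integers(1, 20, n_hit)) % 20
    return seq


def _decode(arr: np.ndarray) -> str:
    return _AA_ARR[arr].tobytes().decode("ascii")


def generate(spec: SyntheticSpec) -> tuple[dict[str, list[GeneModel]], GroundTruth]:
    """Generate per-genome model sets plus ground truth.

    Family member IDs are ``<tag>.g<family index>``; injected fragments
    append ``.f``.  The IDs encode genome and family for auditability but
    are opaque to the pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    ordered_tags = tuple(sorted(spec.tags))
    models: dict[str, list[GeneModel]] = {tag: [] for tag in ordered_tags}
    memberships: dict[str, tuple[str, ...]] = {}
    rows: dict[str, list[int]] = {}

    for idx, pattern in enumerate(spec.patterns(), start=1):
        length = int(np.clip(round(rng.normal(spec.mean_len, spec.len_sd)),
                             spec.min_len, None))
        ancestor = rng.integers(0, 20, length).astype(np.uint8)
        member_ids = []
        for tag in pattern:
            seq = _mutate(ancestor, spec.sub_rate, rng)
            gid = f"{tag}.g{idx:05d}"
            models[tag].append(GeneModel(id=gid, genome=tag, sequence=_decode(seq)))
            member_ids.append(gid)
        name = member_ids[0]  # first-appearance: tags iterated ascending
        memberships[name] = tuple(member_ids)
        rows[name] = [1 if t in pattern else 0 for t in ordered_tags]

    fragments: dict[str, str] = {}
    for tag in ordered_tags:
        for parent in list(models[tag]):
            if rng.random() >= spec.fragment_rate:
                continue
            frac = rng.uniform(0.3, 0.7)
            flen = min(parent.length - 1, max(30, round(frac * parent.length)))
            if rng.random() < 0.5:
                seq = parent.sequence[:flen]
            else:
                seq = parent.sequence[-flen:]
            fid = f"{parent.id}.f"
            models[tag].append(GeneModel(id=fid, genome=tag, sequence=seq))
            fragments[fid] = parent.id

    presence = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(ordered_tags), dtype="int8")
    presence = presence.sort_index()
    truth = GroundTruth(presence=presence, memberships=memberships,
                        fragments=fragments)
    return models, truth


def genome_set_for(spec: SyntheticSpec, directory: str | Path | None = None,
                   groups: Mapping[str, Sequence[str]] | None = None) -> GenomeSet:
    """A GenomeSet matching the fixture, optionally pointing at the FASTA
    files of a written fixture directory."""
    directory = Path(directory) if directory is not None else None
    entries = [
        GenomeEntry(tag=tag, name=f"synthetic genome {tag}",
                    fasta=(directory / f"{tag}.fasta") if directory else None)
        for tag in sorted(spec.tags)
    ]
    return GenomeSet(entries=entries,
                     groups={k: tuple(v) for k, v in (groups or {}).items()})


def write_fixture(models: Mapping[str, Sequence[GeneModel]], truth: GroundTruth,
                  directory: str | Path, spec: SyntheticSpec | None = None) -> None:
    """Write one FASTA per genome, the truth matrix in the spreadsheet
    dialect, the fragment manifest, and (when given) the generating
    parameters echoed back as JSON plus a ready-to-run pipeline config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tag in sorted(models):
        write_fasta(models[tag], directory / f"{tag}.fasta")
    write_matrix(truth.matrix(), directory / "truth_matrix.tsv")
    with open(directory / "fragments.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for fid in sorted(truth.fragments):
            fh.write(f"{fid}\t{truth.fragments[fid]}\n")
    if spec is not None:
        payload = dataclasses.asdict(spec)
        with open(directory / "spec.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=list)
            fh.write("\n")
        _write_config(spec, directory)


def _write_config(spec: SyntheticSpec, directory: Path) -> None:
    import yaml

    config = {
        "genomes": [
            {"tag": tag, "name": f"synthetic genome {tag}",
             "fasta": f"{tag}.fasta"}
            for tag in sorted(spec.tags)
        ],
        "threshold": {"max_evalue": 1e-4},
        "backend": "builtin",
        "require_reciprocal": True,
        "groups": {},
        "outdir": "out",
        "seed": spec.seed,
    }
    with open(directory / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
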