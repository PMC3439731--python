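"""Run configuration: one YAML file naming genomes, thresholds and groups.

Schema::

    genomes:                 # required; processed in ascending tag order
      - tag: am              # 2-8 lowercase letters, unique
        name: Amphimedon queenslandica
        fasta: fixtures/am.fasta       # relative to the config file
    threshold:
      max_evalue: 1.0e-4     # inclusive significance cutoff
    groups:                  # named tag subsets -> derived OR columns
      Bilateria: [br, da, ho, lo, sa, ur]
    backend: builtin         # or "tabular:<directory of hit tables>"
    require_reciprocal: true
    outdir: out
    seed: 42                 # only used by fixture generation
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .io_formats import GenomeEntry, GenomeSet
from .similarity import DEFAULT_PARAMS, AlignmentParams, SimilarityThreshold


@dataclass
class RunConfig:
    genome_set: GenomeSet
    threshold: SimilarityThreshold = field(default_factory=SimilarityThreshold)
    params: AlignmentParams = DEFAULT_PARAMS
    backend: str = "builtin"
    require_reciprocal: bool = True
    outdir: Path = Path("out")
    seed: int = 42

    def __post_init__(self) -> None:
        if self.backend != "builtin" and not self.backend.startswith("tabular:"):
            raise ConfigError(
                f"backend must be 'builtin' or 'tabular:<dir>', got {self.backend!r}")

    @property
    def tabular_dir(self) -> Path | None:
        if self.backend.startswith("tabular:"):
            return Path(self.backend.split(":", 1)[1])
        return None


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict) or not isinstance(raw.get("genomes"), list):
        raise ConfigError(f"{path}: config must be a mapping with a 'genomes' list")

    base = path.parent
    entries = []
    for item in raw["genomes"]:
        if not isinstance(item, dict) or "tag" not in item:
            raise ConfigError(f"{path}: each genome needs at least a 'tag'")
        fasta = item.get("fasta")
        entries.append(GenomeEntry(
            tag=str(item["tag"]),
            name=str(item.get("name", item["tag"])),
            fasta=(base / fasta) if fasta else None,
        ))
    groups = {
        str(k): tuple(str(t) for t in v)
        for k, v in (raw.get("groups") or {}).items()
    }
    try:
        genome_set = GenomeSet(entries=entries, groups=groups)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    thr_raw = raw.get("threshold") or {}
    threshold = SimilarityThreshold(
        max_evalue=float(thr_raw.get("max_evalue", 1e-4)))
    backend = str(raw.get("backend", "builtin"))
    if backend.startswith("tabular:"):
        backend = "tabular:" + str(base / backend.split(":", 1)[1])
    outdir_raw = raw.get("outdir", "out")
    outdir = Path(outdir_raw)
    if not outdir.is_absolute():
        outdir = base / outdir
    return RunConfig(
        genome_set=genome_set,
        threshold=threshold,
        backend=backend,
        require_reciprocal=bool(raw.get("require_reciprocal", True)),
        outdir=outdir,
        seed=int(raw.get("seed", 42)),
    )
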