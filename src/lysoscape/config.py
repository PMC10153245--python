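"""Run configuration: the detector's tunable parameters, YAML round-trip.

Field names follow the classic command-line flags of compositional prophage
finders (``--number``, ``--min-contig-len``, ...) so configurations read
familiarly; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    number: int = 5  # minimum genes per kept region
    min_contig_len: int = 5000
    phage_genes: int = 1  # phage-annotated genes (or hits) required to keep
    extra_dna: int = 2000  # flank searched for att repeats, bp
    min_repeat_len: int = 10
    randomforest_trees: int = 500
    window_size: int = 30  # ORFs per feature window
    threads: int = 2
    metrics: tuple[str, ...] = (
        "median_orf_len",
        "same_strand_run",
        "phage_kmer_score",
        "gc_skew_dev",
        "at_skew_dev",
    )
    training_set: str | None = None
    phmms: str | None = None
    gap_tolerance: int = 2  # host-predicted ORFs tolerated inside a run
    kmer_k: int = 12
    threshold: float = 0.5  # classifier decision threshold
    phage_tokens: tuple[str, ...] = (
        "phage", "prophage", "integrase", "capsid", "tail", "terminase", "portal",
    )
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        d["phage_tokens"] = list(d["phage_tokens"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError(f"config must be a mapping, got {type(data).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("metrics", "phage_tokens"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(data or {})
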