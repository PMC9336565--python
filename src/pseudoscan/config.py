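"""Run configuration: detection thresholds, config-file loading, provenance.

Precedence when resolving a run configuration is CLI flags > config file >
documented defaults. Unknown keys and out-of-bounds values are rejected
eagerly so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Tunable pseudogene-detection cutoffs.

    ``length_ratio_min`` is the fraction of the mean top-homolog length
    below which a gene is called truncated (strict inequality: a gene at
    exactly the cutoff is not flagged); ``length_ratio_max`` mirrors it for
    run-on ORFs. ``min_hits_for_eval`` genes with fewer homologs are left
    unevaluated rather than classified. The dS gate (``ds_min``/``ds_max``)
    restricts dN/dS interpretation to a trustworthy synonymous-divergence
    window.
    """

    length_ratio_min: float = 0.75
    length_ratio_max: float = 1.25
    use_sd_rule: bool = False
    sd_k: float = 2.0
    shared_hit_fraction: float = 0.5
    min_hits_for_eval: int = 3
    intergenic_evalue: float = 1e-5
    intergenic_min_length: int = 90
    dnds_max: float = 0.30
    frameshift_impact_max: float = 0.10
    evalue: float = 1e-4
    max_hits: int = 15
    ds_min: float = 0.01
    ds_max: float = 3.0
    min_identity: float = 0.0  # percent-identity floor applied to hits

    def __post_init__(self):
        if not (0 < self.length_ratio_min <= 1 <= self.length_ratio_max):
            raise ConfigError(
                "require 0 < length_ratio_min <= 1 <= length_ratio_max"
            )
        if not (0 < self.shared_hit_fraction <= 1):
            raise ConfigError("shared_hit_fraction must be in (0, 1]")
        for name in ("sd_k", "intergenic_evalue", "intergenic_min_length",
                     "dnds_max", "frameshift_impact_max", "evalue",
                     "max_hits", "ds_min", "ds_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_hits_for_eval < 1:
            raise ConfigError("min_hits_for_eval must be >= 1")
        if self.min_identity < 0:
            raise ConfigError("min_identity must be >= 0")

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """Fully resolved parameters for one run."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    engine: str = "builtin"
    seed: int = 0
    threads: int = 1
    outdir: str = "pseudoscan_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        return d


_THRESHOLD_KEYS = {f.name for f in dataclasses.fields(Thresholds)}
_TOP_KEYS = {"engine", "seed", "threads", "outdir"}


def resolve_config(defaults: RunConfig | None = None,
                   config_file: str | None = None,
                   flags: dict | None = None) -> RunConfig:
    """Merge defaults, an optional YAML config file, and CLI flags.

    Flags win over the file, the file over defaults. Keys not recognised as
    either a threshold or a top-level run option raise :class:`ConfigError`
    naming the offender; threshold bounds are re-validated on the merged
    result.
    """
    base = defaults or RunConfig()
    merged = base.to_dict()
    thr = dict(merged.pop("thresholds"))

    def apply(source: dict, origin: str):
        for key, value in source.items():
            if value is None:
                continue
            if key in _THRESHOLD_KEYS:
                thr[key] = value
            elif key in _TOP_KEYS:
                merged[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r} ({origin})")

    if config_file:
        with open(config_file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {config_file} is not a mapping")
        apply(loaded, config_file)
    if flags:
        apply(flags, "command line")
    return RunConfig(thresholds=Thresholds(**thr), **merged)


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_log(outdir: str, config: RunConfig, engine_id: str,
            input_checksums: dict, extra: dict | None = None) -> str:
    """Record full provenance for a run: parameters, seed, input checksums.

    Writes ``parameters.json`` (stable, timestamp-free, so identical runs
    produce identical files) plus a human-readable ``run.log``. Returns the
    JSON path.
    """
    os.makedirs(outdir, exist_ok=True)
    from . import __version__

    record = {
        "tool": "pseudoscan",
        "version": __version__,
        "engine": engine_id,
        "config": config.to_dict(),
        "inputs": dict(sorted(input_checksums.items())),
    }
    if extra:
        record["extra"] = extra
    path = os.path.join(outdir, "parameters.json")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(f"pseudoscan {__version__} | engine={engine_id}\n")
        for k, v in sorted(input_checksums.items()):
            fh.write(f"input {k} sha256={v}\n")
        for k, v in sorted(config.to_dict().items()):
            fh.write(f"config {k}={v}\n")
    return path
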