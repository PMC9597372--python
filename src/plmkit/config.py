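"""Run configuration, species presets and reproducible run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .genomic_io import FIVE_PRIME, THREE_PRIME


@dataclass
class RunConfig:
    """All tunable constants of one detection run.

    Defaults are the method's canonical settings: a 99% prediction band,
    score threshold 2 (strict), a 500-position neutral region, redundancy
    Jaccard thresholds 0.9 (genes) / 0.5 (windows), PWM-match q < 0.05,
    up to 5 mismatches in full-length miRNA validation, and a 30-base
    footprint flank.
    """

    side: str = FIVE_PRIME
    upstream_extent: int = 1000
    downstream_extent: int = 500
    kmin: int = 4
    kmax: int = 8
    confidence: float = 0.99
    score_min: float = 2.0
    neutral_length: int = 500
    group_scheme: str | None = None
    gene_jaccard: float = 0.9
    window_jaccard: float = 0.5
    q_threshold: float = 0.05
    max_mismatch: int = 5
    flank: int = 30
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown side {self.side!r}")
        if not (0.5 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0.5, 1)")
        for name in ("gene_jaccard", "window_jaccard"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.neutral_length < 3:
            raise ValueError("neutral_length must be >= 3")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# Species/side presets: extents on the sense axis and the published
# positional group intervals (see plm_core.GROUP_SCHEMES).
PRESETS: dict[str, dict] = {
    "at5p": dict(side=FIVE_PRIME, upstream_extent=1000, downstream_extent=500,
                 group_scheme="at5p"),
    "at3p": dict(side=THREE_PRIME, upstream_extent=500, downstream_extent=1000,
                 group_scheme="at3p"),
    "zm5p": dict(side=FIVE_PRIME, upstream_extent=1500, downstream_extent=500,
                 group_scheme="zm5p"),
    "zm3p": dict(side=THREE_PRIME, upstream_extent=500, downstream_extent=1500,
                 group_scheme="zm3p"),
}


def preset_config(name: str, **overrides) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    data = dict(PRESETS[name])
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(
    config: RunConfig,
    inputs: dict[str, str | Path],
    package_version: str,
    stage_counts: dict[str, int] | None = None,
) -> dict:
    """Reproducibility record: config, input digests, seed, stage counts.

    Raises before any digesting if an input file is missing.
    """
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r}: {path} does not exist")
    return {
        "package_version": package_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "inputs": {name: {"path": str(path), "sha256": _digest(path)}
                   for name, path in inputs.items()},
        "stage_counts": dict(stage_counts or {}),
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def config_digest(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
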