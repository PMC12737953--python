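"""Run configuration: every tunable of the pipeline in one serializable tree.

The defaults *are* the emulated study conditions; ``RunConfig.zero_noise()``
gives the same design with all stochastic array noise removed, under which
the pipeline must recover the implanted truth exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genome import GenomeLayout
from .simulate import ArrayNoise

__all__ = [
    "CallerConfig",
    "FilterSettings",
    "DetectConfig",
    "WgsConfig",
    "RunConfig",
    "PAPER_EVENTS",
]

#: the study's truth ledger: two ancestral terminal tetrasomic regions shared
#: by every plant (background), one heritable B-homeolog terminal deletion
#: arising at generation 4, one whole-set ABBB in a generation-7 plant that
#: also carries the deletion, and one transient whole-set ABBB at generation 6
PAPER_EVENTS: list[dict] = [
    {"plant": "T", "kind": "AAAA", "chrom_set": 3, "start": 9_000_000,
     "end": 10_000_000, "heritable": True},
    {"plant": "T", "kind": "BBBB", "chrom_set": 7, "start": 0,
     "end": 1_000_000, "heritable": True},
    {"plant": "T.3.3.1.1_G1", "kind": "DELETION_B", "chrom_set": 1, "start": 0,
     "end": 3_000_000, "heritable": True},
    {"plant": "T.3.3.1.1.1.1.11_G1", "kind": "ABBB", "chrom_set": 2, "start": 0,
     "end": 10_000_000, "heritable": True},
    {"plant": "T.3.5.1.1.1.1_G2", "kind": "ABBB", "chrom_set": 5, "start": 0,
     "end": 10_000_000, "heritable": False},
]

#: the five plants selected for whole-genome sequencing
SEQUENCED_PLANTS = (
    "T.3.3.1.1.1.1.11_G1",
    "T.3.3.1.1.1.1.13_G1",
    "T.3.3.1.1.1.1.14_G1",
    "T.3.5.1.1.1.1_G2",
    "T.3.5.1.1.1.1.1_G2",
)


@dataclass
class CallerConfig:
    method: str = "bins"
    low_intensity_threshold: float = 0.7
    min_confidence: float = 0.95


@dataclass
class FilterSettings:
    exclude_noisy_samples: bool = True
    noisy_sample_k_sd: float = 4.0


@dataclass
class DetectConfig:
    min_run: int = 2
    background_threshold: float = 0.5


@dataclass
class WgsConfig:
    enabled: bool = True
    depth: float = 30.0
    site_spacing: int = 5000
    window_size: int = 1_000_000
    min_sites: int = 20
    tolerance: float = 0.35
    sequenced_plants: tuple[str, ...] = SEQUENCED_PLANTS


@dataclass
class RunConfig:
    seed: int = 0
    layout: GenomeLayout = field(default_factory=GenomeLayout)
    b_high_frac: float = 0.4
    noise: ArrayNoise = field(default_factory=ArrayNoise)
    events: list[dict] = field(default_factory=lambda: [dict(e) for e in PAPER_EVENTS])
    n_qc_fail_samples: int = 2
    n_noisy_samples: int = 4
    noisy_cell_prob: float = 0.08
    caller: CallerConfig = field(default_factory=CallerConfig)
    filters: FilterSettings = field(default_factory=FilterSettings)
    detect: DetectConfig = field(default_factory=DetectConfig)
    wgs: WgsConfig = field(default_factory=WgsConfig)

    @classmethod
    def zero_noise(cls, seed: int = 0, **kwargs) -> "RunConfig":
        """Study design with all stochastic array noise and bad samples off."""
        return cls(
            seed=seed,
            noise=ArrayNoise.none(),
            n_qc_fail_samples=0,
            n_noisy_samples=0,
            **kwargs,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "layout" in d and isinstance(d["layout"], dict):
            d["layout"] = GenomeLayout(**d["layout"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = ArrayNoise(**d["noise"])
        for key, klass in (
            ("caller", CallerConfig),
            ("filters", FilterSettings),
            ("detect", DetectConfig),
            ("wgs", WgsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "wgs" and "sequenced_plants" in sub:
                    sub["sequenced_plants"] = tuple(sub["sequenced_plants"])
                d[key] = klass(**sub)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists for YAML/JSON friendliness."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
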