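"""Run configuration: YAML schema, validation, seed fan-out, echoing.

A single top-level seed reproduces an entire run: per-stage seeds are derived
with ``numpy.random.SeedSequence([seed, stage_tag])`` so stages are
statistically independent but jointly reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifiers import DisputeModelSpec, GlobalModelSpec
from .dispute import DEFAULT_THRESHOLD
from .synth import GeneratorConfig

__all__ = ["RunConfig", "ConfigError", "stage_seed"]

_STAGE_TAGS = {"simulate": 11, "preprocess": 12, "folds": 13, "train": 14, "report": 15}


class ConfigError(ValueError):
    pass


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage seed (< 2**31) from the run seed."""
    return int(np.random.SeedSequence([seed, _STAGE_TAGS[stage]]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "finspec_out"
    dataset_csv: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    k: int = 4
    folds: list[int] | None = None
    fusion_policy: str = "mode_priority"
    priority: tuple[str, ...] = ("Fluor", "VNIR", "SWIR")
    modes: tuple[str, ...] = ("Fluor", "VNIR", "SWIR")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    global_spec: GlobalModelSpec = field(default_factory=GlobalModelSpec)
    dispute_spec: DisputeModelSpec = field(default_factory=DisputeModelSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        try:
            for key, klass in (("generator", GeneratorConfig),
                               ("global_spec", GlobalModelSpec),
                               ("dispute_spec", DisputeModelSpec)):
                if key in kwargs:
                    sub = kwargs[key]
                    sub_known = {f.name for f in dataclasses.fields(klass)}
                    sub_unknown = set(sub) - sub_known
                    if sub_unknown:
                        raise ConfigError(f"unknown {key} keys: {sorted(sub_unknown)}")
                    sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
                    kwargs[key] = klass(**sub)
            for key in ("priority", "modes"):
                if key in kwargs:
                    kwargs[key] = tuple(kwargs[key])
            return cls(**kwargs)
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err

    def echo(self, outdir: str | Path) -> None:
        """Write the full effective config into the output directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "effective_config.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str)
        )
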