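"""Run configuration: one serialisable object driving the whole pipeline.

A run's resolved configuration is written into its output directory, and
re-running from that stored copy reproduces all CSV outputs bit-identically
(every stochastic stage derives its seed from the stored one).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    profile: str = "paper-scale"
    seed: int = 1
    out_dir: str = "stiffmorph_run"
    # stage toggles
    run_segmentation_outputs: bool = False  # write per-scene masks/TIFFs
    run_k_selection: bool = True
    run_classification: bool = True
    run_stats: bool = True
    # thresholds
    min_object_um2: float = 20.0
    clump_min_size: int = 3
    r_threshold: float = 0.8
    test_frac: float = 0.1
    k: int | None = None  # override the selected k
    k_min: int = 2
    k_max: int = 6
    rf_search_draws: int = 50
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg

    @classmethod
    def show_defaults(cls) -> str:
        return yaml.safe_dump(asdict(cls()), sort_keys=True)
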