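"""Run configuration with the analysis' default thresholds.

Defaults are the decision thresholds the whole analysis is built around:
2 kb length screen, 0.90/0.01 detector score cut, 5% BUSCO ratio, 50%
completeness, 95%/70% dereplication, 10% two-sided depth trim, 30/50/50/50
protein-hit filter, one-fifth / 10-protein family votes, 45 spacer
bit-score, 90%/30% host alignment, alpha = 0.05, five repeats of fivefold
CV, and top-5 feature union.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .synthgen import SimConfig

__all__ = ["RunConfig", "demo_config_path"]


def demo_config_path() -> Path:
    """Path of the bundled small demo run configuration."""
    return Path(__file__).parent / "data" / "demo_config.json"


@dataclass
class RunConfig:
    seed: int = 0
    # triage
    min_contig_length: int = 2000  # strict: length must exceed this
    # clustering
    cluster_identity: float = 95.0
    cluster_coverage: float = 0.70
    cluster_strict: bool = False
    # signatures
    alpha: float = 0.05
    min_prevalence: float = 0.10
    # diversity
    n_permutations: int = 999
    # ml
    rf_n_estimators: int = 500
    cv_repeats: int = 5
    cv_folds: int = 5
    top_k: int = 5
    # simulation (None -> pipeline expects inputs on disk)
    sim: SimConfig | None = None
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim is not None:
            if "genome_length_range" in sim:
                sim["genome_length_range"] = tuple(sim["genome_length_range"])
            cfg.sim = SimConfig(**sim)
            cfg.sim.validate()
        return cfg

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, default=list) + "\n")
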