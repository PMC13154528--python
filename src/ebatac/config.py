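"""TOML pipeline configuration with strict key checking.

Unset keys fall back to documented defaults; unknown keys are an error
(no silent typos).  A handful of sections are open mappings whose keys
are data rather than schema (cell counts per stage, marker panels) and
are validated downstream instead.

The default QC thresholds here are scaled for synthetic libraries, whose
per-cell depths are orders of magnitude below a real high-depth
plate-based library; :func:`ebatac.qc.filter_cells` itself defaults to
the real-data thresholds (fragments in [10^4.5, 10^5], log10 TSS reads
in [3.5, 4.5]).
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .simulate import DEFAULT_CELLS, DEFAULT_MARKER_TFS, STAGES, SimDesign, substream_seed

STAGE_ORDER = (
    "simulate", "qc", "matrices", "consistency",
    "cluster", "trajectory", "loops", "network",
)

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "ebatac_run",
    "stages": list(STAGE_ORDER),
    "simulate": {
        "cells_per_type_per_stage": {s: dict(DEFAULT_CELLS[s]) for s in STAGES},
        "n_genes": 300,
        "n_tfs": 28,
        "enhancers_per_target": 1,
        "marker_tfs": {t: list(v) for t, v in DEFAULT_MARKER_TFS.items()},
        "regulon_size": 8,
        "master_regulon_boost": 2,
        "p0": 0.05,
        "p1": 0.85,
        "alpha": 0.5,
        "depth_mu": 2.1,
        "depth_sigma": 0.35,
        "bg_rate": 40.0,
        "motif_bg_rate": 0.001,
    },
    "qc": {
        "flank_bp": 2000,
        "center_bp": 50,
        "edge_bp": 100,
        "pseudocount": 0.1,
        "min_frag": 100.0,       # scaled for synthetic library depths
        "max_frag": 100000.0,
        "min_log10_tss": 1.5,
        "max_log10_tss": 4.5,
    },
    "matrices": {
        "n_components": 30,
        "binarize": True,
        "decay_bp": 5000,
        "max_dist": 100000,
        "scale": 10000.0,
        "n_background": 50,
        # neighbor pool widened for desk-scale peak sets: 50-of-600 peaks
        # cannot span diverse programs the way 50-of-10^5 does in real data
        "n_neighbors": 250,
    },
    "consistency": {"k": 10},
    "cluster": {
        "k": 7,
        "n_init": 50,
        "max_iter": 300,
        "tau": 0.25,
        "panel": {t: list(v) for t, v in DEFAULT_MARKER_TFS.items()},
    },
    "trajectory": {"n_components": 6, "n_bins": 10},
    "loops": {
        "target_size": 10,
        "min_dist": 1000,
        "max_dist": 500000,
        "threshold": 0.35,
    },
    "network": {"tss_window": 2000},
    "paths": {
        "fragments": "",
        "peaks": "",
        "counts": "",
        "counts_peaks": "",
        "counts_barcodes": "",
        "genes": "",
        "motifs": "",
        "stages_table": "",
    },
}

#: dotted paths whose sub-keys are data, not schema
OPEN_MAPS = {
    "simulate.cells_per_type_per_stage",
    "simulate.marker_tfs",
    "cluster.panel",
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        path = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path!r}")
        default = defaults[key]
        if isinstance(default, dict) and path not in OPEN_MAPS:
            if not isinstance(value, dict):
                raise ConfigError(f"{path!r} must be a table")
            out[key] = _merge(default, value, prefix=f"{path}.")
        else:
            if isinstance(default, bool):
                ok = isinstance(value, bool)
            elif isinstance(default, float):
                ok = isinstance(value, (int, float)) and not isinstance(value, bool)
            elif isinstance(default, int):
                ok = isinstance(value, int) and not isinstance(value, bool)
            elif isinstance(default, str):
                ok = isinstance(value, str)
            elif isinstance(default, (list, dict)):
                ok = isinstance(value, type(default))
            else:
                ok = True
            if not ok:
                raise ConfigError(
                    f"{path!r} has type {type(value).__name__}, "
                    f"expected {type(default).__name__}"
                )
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class PipelineConfig:
    data: dict[str, Any]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    @property
    def stages(self) -> list[str]:
        return list(self.data["stages"])

    def section(self, name: str) -> dict[str, Any]:
        return self.data[name]

    def stage_seed(self, stage: str) -> int:
        return substream_seed(self.seed, stage)

    def design(self) -> SimDesign:
        sim = self.section("simulate")
        return SimDesign(
            cells_per_type_per_stage={
                s: dict(v) for s, v in sim["cells_per_type_per_stage"].items()
            },
            n_genes=sim["n_genes"],
            n_tfs=sim["n_tfs"],
            enhancers_per_target=sim["enhancers_per_target"],
            marker_tfs={t: list(v) for t, v in sim["marker_tfs"].items()},
            regulon_size=sim["regulon_size"],
            master_regulon_boost=sim["master_regulon_boost"],
            p0=sim["p0"],
            p1=sim["p1"],
            alpha=sim["alpha"],
            depth_mu=sim["depth_mu"],
            depth_sigma=sim["depth_sigma"],
            bg_rate=sim["bg_rate"],
            motif_bg_rate=sim["motif_bg_rate"],
            seed=self.stage_seed("simulate"),
        )

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigError(
                f"unknown stages {unknown}; valid stages are {list(STAGE_ORDER)}"
            )
        if not isinstance(self.data["seed"], int):
            raise ConfigError("seed must be an integer")


def default_config(**overrides: Any) -> PipelineConfig:
    """The documented defaults, with optional top-level overrides."""
    cfg = PipelineConfig(_merge(DEFAULTS, overrides))
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    """Parse a TOML file, fill defaults, reject unknown keys."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    cfg = PipelineConfig(_merge(DEFAULTS, user))
    cfg.validate()
    return cfg
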