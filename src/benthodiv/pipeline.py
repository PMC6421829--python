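"""One-config orchestration: simulate/load -> filter -> alpha -> beta ->
PERMANOVA screens, with a run manifest and resumable stages.

DNA and RNA arms run in parallel through every stage, share the tree, and
are never pooled in any statistical model.  Every stage writes its outputs
under the run directory plus a sentinel carrying the config hash;
``resume=True`` skips stages whose sentinel matches the current config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as bio
from .alpha import AlphaProfile, alpha_profile, species_accumulation
from .beta import MEASURES, distance_matrix
from .env_stats import (
    alpha_env_screen,
    beta_env_screen,
    correlation_matrix,
    drop_low_depth,
    function_screen,
)
from .alpha import rarefy_counts
from ._utils import derive_rng
from .synthetic import SyntheticConfig, simulate_dataset
from .tables import CountTable, EnvTable

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("benthodiv.pipeline")

#: analysis defaults: DNA/RNA rarefaction depths, 100 alpha iterations,
#: 999 rarefactions x 999 permutations, significance at p <= 0.05
FULL_PROFILE = {"iterations": 100, "rarefactions": 999, "permutations": 999}
#: scaled-down profile for desk/CI runs
DESK_PROFILE = {"iterations": 20, "rarefactions": 50, "permutations": 99}


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "benthodiv_run"
    simulate: dict | None = None
    inputs: dict | None = None
    depths: dict = field(default_factory=lambda: {"DNA": 9058, "RNA": 4941})
    iterations: int = 100
    rarefactions: int = 999
    permutations: int = 999
    measures: list = field(default_factory=lambda: list(MEASURES))
    alpha_level: float = 0.05
    coverage_method: str = "mean_curve"

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs'")
        if self.simulate is not None and self.inputs is not None:
            raise ValueError("'simulate' and 'inputs' are mutually exclusive")
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise ValueError(f"unknown measure(s): {unknown}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config key(s): {sorted(extra)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    def apply_profile(self, profile: str) -> "PipelineConfig":
        if profile == "full":
            updates = FULL_PROFILE
        elif profile == "desk":
            updates = DESK_PROFILE
        else:
            raise ValueError(f"unknown profile {profile!r}")
        return dataclasses.replace(self, **updates)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (where outputs land is excluded,
        so identical analyses in different directories share a hash)."""
        d = self.to_dict()
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig, data_dir: Path):
    if cfg.simulate is not None:
        syn = SyntheticConfig(seed=cfg.seed, **cfg.simulate)
        ds = simulate_dataset(syn, out_dir=data_dir)
        return ds.counts, ds.env, ds.tree, ds.functions
    paths = cfg.inputs
    counts = bio.read_count_table(paths["counts"],
                                  transpose=bool(paths.get("transpose", False)))
    env = bio.read_env_table(paths["env"], companion=counts)
    if env.fraction is not None:
        counts.fraction = {s: env.fraction[s] for s in counts.sample_ids
                           if s in env.fraction.index}
    tree = bio.read_tree(paths["tree"]) if paths.get("tree") else None
    functions = (bio.read_function_table(paths["functions"])
                 if paths.get("functions") else None)
    return counts, env, tree, functions


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    Fails fast on inconsistent requests (e.g. a UniFrac measure with no
    tree) before any computation.  The manifest records versions, seed,
    config hash and per-stage wall time.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict[str, Any] = {
        "benthodiv_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": chash,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    def stage_done(name: str) -> bool:
        sentinel = out / f".stage_{name}.done"
        return resume and sentinel.exists() and sentinel.read_text().strip() == chash

    def mark_done(name: str, t0: float) -> None:
        (out / f".stage_{name}.done").write_text(chash + "\n")
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}

    meta = {"seed": config.seed, "config_hash": chash, "version": __version__}

    # stage: data ------------------------------------------------------
    t0 = time.time()
    data_dir = out / "data"
    counts, env, tree, functions = _load_inputs(config, data_dir)
    # pre-flight validation before any statistics
    if any(m.startswith("unifrac") for m in config.measures) and tree is None:
        raise ValueError("UniFrac measure requested but no tree available")
    arms = counts.split_fractions() if counts.fraction else {"DNA": counts}
    for frac in arms:
        if frac not in config.depths:
            raise ValueError(f"no rarefaction depth configured for fraction {frac}")
    if not stage_done("data"):
        mark_done("data", t0)

    # stage: filter ----------------------------------------------------
    t0 = time.time()
    filtered: dict[str, CountTable] = {}
    reports = {}
    for frac, arm in arms.items():
        filtered[frac], reports[frac] = drop_low_depth(arm, config.depths[frac])
    if not stage_done("filter"):
        bio.write_results(reports, out / "filter_report.json", metadata=meta)
        mark_done("filter", t0)

    # stage: alpha -----------------------------------------------------
    t0 = time.time()
    alpha_dir = out / "alpha"
    profiles: dict[str, AlphaProfile] = {}
    if stage_done("alpha"):
        for frac in filtered:  # reload finished per-sample profiles
            data = pd.read_csv(alpha_dir / f"alpha_{frac}.tsv", sep="\t",
                               comment="#", index_col=0)
            profiles[frac] = AlphaProfile(data, config.depths[frac],
                                          config.iterations, config.seed)
    else:
        for frac, arm in filtered.items():
            profiles[frac] = alpha_profile(
                arm, tree, depth=config.depths[frac],
                iterations=config.iterations, seed=config.seed,
                coverage_method=config.coverage_method,
            )
            bio.write_results(profiles[frac].data, alpha_dir / f"alpha_{frac}.tsv",
                              metadata=meta)
            bio.write_results(profiles[frac].mean_curves,
                              alpha_dir / f"rarefaction_curves_{frac}.tsv",
                              metadata=meta)
            bio.write_results(species_accumulation(filtered[frac]),
                              alpha_dir / f"accumulation_{frac}.tsv", metadata=meta)
        mark_done("alpha", t0)

    # stage: beta (representative single-rarefaction matrices) ---------
    t0 = time.time()
    if not stage_done("beta"):
        beta_dir = out / "beta"
        for frac, arm in filtered.items():
            rarefied = rarefy_counts(
                arm, config.depths[frac],
                rng=derive_rng(config.seed, f"beta-{frac}"),
            )
            for m in config.measures:
                D = distance_matrix(rarefied, m, tree)
                bio.write_results(D, beta_dir / f"distance_{frac}_{m}.tsv",
                                  metadata=meta)
        mark_done("beta", t0)

    # stage: screens ---------------------------------------------------
    t0 = time.time()
    if not stage_done("screens"):
        screen_dir = out / "screens"
        station_env = EnvTable(env.data.drop_duplicates())
        bio.write_results(correlation_matrix(station_env).tidy(config.alpha_level),
                          screen_dir / "env_correlations.tsv", metadata=meta)
        bio.write_results(alpha_env_screen(profiles, env, alpha=config.alpha_level),
                          screen_dir / "alpha_screen.tsv", metadata=meta)
        bio.write_results(
            beta_env_screen(
                counts, env, tree, config.depths,
                rarefactions=config.rarefactions, n_perm=config.permutations,
                seed=config.seed, measures=config.measures,
                alpha=config.alpha_level,
            ),
            screen_dir / "beta_screen.tsv", metadata=meta,
        )
        if functions is not None:
            bio.write_results(
                function_screen(functions, env, n_perm=config.permutations,
                                seed=config.seed, alpha=config.alpha_level),
                screen_dir / "function_screen.tsv", metadata=meta,
            )
        mark_done("screens", t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                       encoding="utf-8")
    log.info("pipeline complete: %s", out)
    return out
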