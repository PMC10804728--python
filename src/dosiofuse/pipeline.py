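"""Benchmark orchestration: configuration, per-cell seeding, resumability.

A benchmark run enumerates strategy x selector x model cells over a
multi-center cohort, runs leave-one-center-out CV per cell, and writes a
tidy CSV (one row per cell x held-out center) plus per-cell JSON provenance.
Completed cells are skipped on re-run (resumable), and each cell's seed is
derived by hashing the cell coordinates with the top-level seed so results
are reproducible without global state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import STRATEGIES, BenchmarkResult, loco_cv
from .models import MODEL_REGISTRY
from .selection import SELECTOR_REGISTRY

__all__ = ["RunConfig", "cell_seed", "run_benchmark"]


@dataclass
class RunConfig:
    """Configuration of a benchmark run."""

    strategy_tables: dict[str, pd.DataFrame]      # strategy -> feature table
    time: np.ndarray
    event: np.ndarray
    centers: np.ndarray
    selectors: list[str] = field(default_factory=lambda: list(SELECTOR_REGISTRY))
    models: list[str] = field(default_factory=lambda: list(MODEL_REGISTRY))
    k: int = 10
    n_boot: int = 1000
    seed: int = 0
    out_dir: Path | None = None
    grids: dict[str, list[dict]] | None = None
    selector_params: dict[str, dict] | None = None

    def validate(self) -> None:
        for s in self.strategy_tables:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for sel in self.selectors:
            if sel not in SELECTOR_REGISTRY:
                raise ValueError(f"unregistered selector {sel!r}")
        for m in self.models:
            if m not in MODEL_REGISTRY:
                raise ValueError(f"unregistered model {m!r}")
        n = len(self.time)
        if not (len(self.event) == len(self.centers) == n):
            raise ValueError("time/event/centers length mismatch")
        for s, t in self.strategy_tables.items():
            if len(t) != n:
                raise ValueError(f"strategy {s} table has {len(t)} rows, expected {n}")


def cell_seed(top_seed: int, strategy: str, selector: str, model: str) -> int:
    """Deterministic per-cell seed from the cell coordinates (< 2**31)."""
    key = f"{top_seed}|{strategy}|{selector}|{model}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31 - 1)


def run_benchmark(config: RunConfig) -> tuple[list[BenchmarkResult], pd.DataFrame]:
    """Execute the full strategy x selector x model grid.

    Returns the per-cell results and the tidy frame (one row per cell and
    held-out center). Cell failures are recorded and do not stop the run.
    """
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    results: list[BenchmarkResult] = []
    frames: list[pd.DataFrame] = []
    failures: list[dict] = []
    for strategy, table in config.strategy_tables.items():
        for selector in config.selectors:
            for model in config.models:
                seed = cell_seed(config.seed, strategy, selector, model)
                cell_path = (
                    out_dir / f"cell_{strategy}_{selector}_{model}.json"
                    if out_dir else None
                )
                if cell_path and cell_path.exists():
                    cached = json.loads(cell_path.read_text())
                    frames.append(pd.DataFrame(cached["rows"]))
                    continue
                try:
                    res = loco_cv(
                        table, (config.time, config.event), config.centers,
                        selector_name=selector, model_name=model,
                        k=config.k, n_boot=config.n_boot, seed=seed,
                        grid=(config.grids or {}).get(model),
                        strategy_label=strategy,
                        selector_params=(config.selector_params or {}).get(selector),
                    )
                except Exception as exc:
                    failures.append({
                        "strategy": strategy, "selector": selector,
                        "model": model, "error": str(exc),
                    })
                    continue
                results.append(res)
                frame = res.to_frame()
                frames.append(frame)
                if cell_path:
                    from . import __version__

                    cell_path.write_text(json.dumps({
                        "strategy": strategy, "selector": selector,
                        "model": model, "seed": seed, "version": __version__,
                        "config_hash": cell_seed(config.seed, "config",
                                                 ",".join(config.selectors),
                                                 ",".join(config.models)),
                        "grand_mean": res.grand_mean, "grand_sd": res.grand_sd,
                        "rows": frame.to_dict(orient="records"),
                    }, indent=2))
    tidy = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out_dir:
        tidy.to_csv(out_dir / "benchmark.csv", index=False)
        (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
    run_benchmark.failures = failures
    return results, tidy
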