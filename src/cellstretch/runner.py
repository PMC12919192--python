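"""Sweep orchestration: run every (waveform, frequency, amplitude) combination,
reduce each to nuclear series and chromatin traces, and write a reproducible
output layout with a manifest.

The mesh is built once and the factorized operators are reused across runs
(the model is linear, so only the time step and constraint pattern matter for
the factorization). Runs are mutually independent; outputs are identical for
any permutation of the sweep order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chromatin import chromatin_sweep, classify_regime, integrate_chromatin
from .config import SweepConfig
from .errors import CellStretchError
from .fem import LoadingProgram, SimulationEngine
from .meshing import mesh_geometry
from .postprocess import extract_nuclear_series, per_cycle_peaks
from .waveforms import (
    load_shape_table,
    make_brachial_waveform,
    make_sine_waveform,
)

__all__ = ["RunManifest", "run_sweep", "run_label"]

log = logging.getLogger("cellstretch")

_FLOAT_FMT = "%.10g"


def run_label(kind: str, freq: float, eps: float) -> str:
    return f"{kind}_f{freq:g}_eps{eps:g}"


@dataclass
class RunManifest:
    """Inventory of a sweep execution."""

    config_hash: str
    version: str
    output_dir: str
    runs: list[dict] = field(default_factory=list)
    files: list[str] = field(default_factory=list)
    elapsed_s: float = 0.0

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def is_complete(self) -> bool:
        """Every completed run has all of its declared files on disk."""
        root = Path(self.output_dir)
        return all(
            (root / f).is_file()
            for run in self.runs
            if run["status"] == "completed"
            for f in run["files"]
        )


def _make_waveform(kind: str, eps: float, freq: float, shape_file=None):
    if kind == "sine":
        return make_sine_waveform(eps, freq)
    table = load_shape_table(shape_file) if shape_file else None
    return make_brachial_waveform(eps, freq, table)


def run_sweep(cfg: SweepConfig, output_dir: str | Path | None = None) -> RunManifest:
    """Execute the full sweep described by ``cfg``.

    Per run: ``nuclear_series.csv``, ``cycle_summary.csv`` and one
    ``chromatin_trace_<phase>.csv`` per configured phase; plus a combined
    ``regimes.csv`` and ``manifest.json`` at the top level. A failing run is
    recorded in the manifest and does not abort the sweep.
    """
    t_start = time.time()
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    geometry = cfg.geometry.as_geometry(cfg.membrane.thickness_um)
    sizing = cfg.mesh.as_sizing()
    log.info("meshing cell geometry (h_max=%g um)", sizing.h_max)
    mesh = mesh_geometry(geometry, sizing)
    engine = SimulationEngine(
        mesh, cfg.materials.as_materials(),
        membrane_thickness=cfg.membrane.thickness_um,
    )

    manifest = RunManifest(
        config_hash=cfg.config_hash(), version=__version__, output_dir=str(out)
    )
    chromatin_entries = []
    params_list = cfg.chromatin.params()

    combos = sorted(
        (kind, freq, eps)
        for kind in cfg.waveforms
        for freq in cfg.frequencies_hz
        for eps in cfg.eps_max_list
    )
    for kind, freq, eps in combos:
        label = run_label(kind, freq, eps)
        run_dir = out / label
        entry = {"label": label, "waveform": kind, "frequency_hz": freq,
                 "eps_max": eps, "status": "completed", "files": []}
        try:
            waveform = _make_waveform(kind, eps, freq, cfg.waveform.shape_file)
            program = LoadingProgram(
                waveform=waveform,
                n_cycles=cfg.loading.n_cycles,
                steps_per_cycle=cfg.solver.steps_per_cycle,
                mode=cfg.loading.mode,
                y_to_x_ratio=cfg.loading.y_to_x_ratio,
                scheme=cfg.solver.scheme,
            )
            log.info("run %s", label)
            history = engine.run(program)
            series = extract_nuclear_series(history, cfg.chromatin.stress_component)
            summary = per_cycle_peaks(series)

            run_dir.mkdir(exist_ok=True)
            series.to_frame().to_csv(
                run_dir / "nuclear_series.csv", index=False, float_format=_FLOAT_FMT
            )
            summary.to_frame().to_csv(
                run_dir / "cycle_summary.csv", index=False, float_format=_FLOAT_FMT
            )
            entry["files"] = [f"{label}/nuclear_series.csv", f"{label}/cycle_summary.csv"]
            entry["xy_ratio_final_cycle"] = summary.xy_ratio

            for p in params_list:
                trace = integrate_chromatin(
                    series.times, series.mean_sigma_xx, p,
                    steps_per_cycle=series.steps_per_cycle,
                )
                fname = f"chromatin_trace_{p.phase}.csv"
                df = trace.to_frame()
                per_cycle = classify_regime(
                    trace, cfg.chromatin.unfold_fold, cfg.chromatin.damage_fold
                )
                spc = series.steps_per_cycle
                cycle_of = [
                    min(max((i + spc - 1) // spc, 1), trace.n_cycles)
                    for i in range(len(df))
                ]
                df["cycle"] = cycle_of
                df["regime"] = [per_cycle[c - 1] for c in cycle_of]
                df.to_csv(run_dir / fname, index=False, float_format=_FLOAT_FMT)
                entry["files"].append(f"{label}/{fname}")
            chromatin_entries.append(
                (
                    {"waveform": kind, "eps_max": eps, "frequency_hz": freq},
                    series.times,
                    series.mean_sigma_xx,
                    series.steps_per_cycle,
                )
            )
        except CellStretchError as exc:
            log.error("run %s failed: %s", label, exc)
            entry["status"] = "failed"
            entry["error"] = str(exc)
        manifest.runs.append(entry)

    regimes = chromatin_sweep(
        chromatin_entries, params_list,
        cfg.chromatin.unfold_fold, cfg.chromatin.damage_fold,
    )
    if len(regimes):
        regimes = regimes.sort_values(
            ["waveform", "frequency_hz", "eps_max", "phase"]
        ).reset_index(drop=True)
    regimes.to_csv(out / "regimes.csv", index=False, float_format=_FLOAT_FMT)

    manifest.files = sorted(
        [f for run in manifest.runs for f in run["files"]] + ["regimes.csv"]
    )
    manifest.elapsed_s = round(time.time() - t_start, 3)
    manifest.save(out / "manifest.json")
    return manifest


def load_regimes(output_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(output_dir) / "regimes.csv")
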