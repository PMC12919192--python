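"""Shared fixtures: one desk-scale mesh/engine per session, a memoized run
cache, and the full default sweep output reused by several test modules."""

from __future__ import annotations

import warnings

import pytest
from hypothesis import HealthCheck, settings

from cellstretch import (
    CellGeometry,
    LoadingProgram,
    MeshSizing,
    SimulationEngine,
    extract_nuclear_series,
    make_brachial_waveform,
    make_sine_waveform,
    mesh_geometry,
)

settings.register_profile(
    "cellstretch",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cellstretch")


@pytest.fixture(scope="session")
def default_geometry():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nucleus tangent to basal plane
        return CellGeometry()


@pytest.fixture(scope="session")
def ci_mesh(default_geometry):
    return mesh_geometry(default_geometry, MeshSizing.ci())


@pytest.fixture(scope="session")
def engine(ci_mesh):
    return SimulationEngine(ci_mesh)


@pytest.fixture(scope="session")
def run_cell(engine):
    """Memoized simulation runner on the shared desk-scale cell model.

    ``run_cell(kind, freq, eps, mode=..., r=...)`` returns the
    ``(FieldHistory, NuclearStrainSeries)`` pair for a 10-cycle run.
    """
    cache: dict = {}

    def _run(kind="sine", freq=0.1, eps=0.075, mode="equibiaxial",
             r=1.0, n_cycles=10):
        key = (kind, freq, eps, mode, r, n_cycles)
        if key not in cache:
            wf = (
                make_sine_waveform(eps, freq)
                if kind == "sine"
                else make_brachial_waveform(eps, freq)
            )
            program = LoadingProgram(
                waveform=wf, n_cycles=n_cycles, mode=mode, y_to_x_ratio=r
            )
            history = engine.run(program)
            cache[key] = (history, extract_nuclear_series(history))
        return cache[key]

    return _run


@pytest.fixture(scope="session")
def sweep_output(tmp_path_factory):
    """Full default-grid sweep (28 runs) at the desk-scale mesh profile."""
    from cellstretch import apply_profile, validate_config
    from cellstretch.runner import run_sweep

    out = tmp_path_factory.mktemp("sweep")
    cfg = apply_profile(validate_config(""), "ci")
    manifest = run_sweep(cfg, out)
    return cfg, manifest, out
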