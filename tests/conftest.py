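"""Shared fixtures: phantoms and full pipeline runs.

The pipeline runs are session-scoped because each takes tens of seconds
at 256x256; several tests interrogate different aspects of the same run.
The phantom study uses a front-snapshot threshold t* = 60 (about 1.5x
the organ's minor semi-axis) so the fast-marching front floods the organ
interior from the seeds and stalls at boundaries before the snapshot.
"""

from __future__ import annotations

import numpy as np
import pytest

import pancseg as ps
from pancseg.config import EnergyConfig, FastMarchingConfig, PipelineConfig

STUDY_SEED = 1
STUDY_T_STAR = 60.0


def study_config(tune: bool = True) -> PipelineConfig:
    return PipelineConfig(
        fm=FastMarchingConfig(t_star=STUDY_T_STAR),
        energy=EnergyConfig(enable_tune=tune),
    )


@pytest.fixture(scope="session")
def phantom_fractured() -> ps.PhantomResult:
    return ps.generate_phantom(ps.PhantomSpec(boundary_gap_fraction=0.3, rng_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def phantom_clean() -> ps.PhantomResult:
    return ps.generate_phantom(ps.PhantomSpec(boundary_gap_fraction=0.0, rng_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def seg_clean_line(phantom_clean):
    ph = phantom_clean
    return ps.run_pipeline(ph.image, ph.seeds, line=ph.line, config=study_config(True))


@pytest.fixture(scope="session")
def seg_frac_line_tuned(phantom_fractured):
    ph = phantom_fractured
    return ps.run_pipeline(ph.image, ph.seeds, line=ph.line, config=study_config(True))


@pytest.fixture(scope="session")
def seg_frac_line_untuned(phantom_fractured):
    ph = phantom_fractured
    return ps.run_pipeline(ph.image, ph.seeds, line=ph.line, config=study_config(False))


@pytest.fixture(scope="session")
def seg_frac_auto_tuned(phantom_fractured):
    ph = phantom_fractured
    return ps.run_pipeline(ph.image, ph.seeds, line=None, config=study_config(True))


@pytest.fixture(scope="session")
def seg_frac_auto_untuned(phantom_fractured):
    ph = phantom_fractured
    return ps.run_pipeline(ph.image, ph.seeds, line=None, config=study_config(False))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
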