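"""Shared fixtures: solved fields and a default synthetic experiment.

The expensive artifacts (sparse solves, the 30-image experiment) are
session-scoped so the whole suite pays for each exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import tuberfield as tf
from tuberfield import synthetic_staining as ss


@pytest.fixture(scope="session")
def config_1000() -> tf.ElectrodeConfig:
    return tf.ElectrodeConfig(applied_voltage_V0=1000.0)


@pytest.fixture(scope="session")
def coarse_grid() -> tf.GridSpec:
    """Fast 40 x 40 mm grid at h = 0.2 mm for unit-level solver tests."""
    return tf.GridSpec(width=40.0, height=40.0, spacing_h=0.2)


@pytest.fixture(scope="session")
def solved_coarse(config_1000, coarse_grid) -> tf.PotentialField:
    return tf.solve_laplace(config_1000, coarse_grid)


@pytest.fixture(scope="session")
def field_default_grid(config_1000) -> tf.FieldMap:
    """|E| for V0 = 1000 V on the default 60 x 60 mm grid, h = 0.1 mm."""
    pf = tf.solve_laplace(config_1000, tf.GridSpec())
    return tf.field_magnitude(pf)


@pytest.fixture(scope="session")
def field_fine(config_1000) -> tf.FieldMap:
    """|E| for V0 = 1000 V at h = 0.05 mm (the accuracy-check resolution)."""
    pf = tf.solve_laplace(config_1000, tf.GridSpec(spacing_h=0.05))
    return tf.field_magnitude(pf)


@pytest.fixture(scope="session")
def zones_by_voltage() -> dict[float, tf.AblationZones]:
    """Predicted zones for the five protocol voltages, default thresholds."""
    return ss.solve_zones_by_voltage(ss.DEFAULT_VOLTAGES)


@pytest.fixture(scope="session")
def default_experiment(zones_by_voltage) -> ss.ExperimentBundle:
    """The default 30-image experiment (5 voltages x 2 modalities x 3 reps)."""
    return ss.generate_experiment(master_seed=42, zones_by_voltage=zones_by_voltage)


@pytest.fixture(scope="session")
def zones_900(zones_by_voltage) -> tf.AblationZones:
    return zones_by_voltage[900.0]
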