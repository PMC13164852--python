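"""Shared fixtures: small synthetic studies and handmade samples."""

from __future__ import annotations

import numpy as np
import pytest

from lrpnet.preprocess import SampleMatrix
from lrpnet.simulate import (
    ALL_POSITIONS,
    CONCENTRATIONS_MM,
    SCREENING_CONCENTRATIONS_MM,
    LeafLevel,
    PositionLabel,
    Region,
    SimulatorConfig,
    reduced_config,
)

TOP_BASAL = PositionLabel(LeafLevel.TOP, Region.BASAL)
PLANTS = ("plant-1", "plant-2", "plant-3")


@pytest.fixture(scope="session")
def short_config() -> SimulatorConfig:
    """One-minute recordings: 2 windows each, fast to simulate."""
    return reduced_config(duration_s=60.0)


def make_fake_samples(
    positions=ALL_POSITIONS,
    concentrations=SCREENING_CONCENTRATIONS_MM,
    plants=PLANTS,
    windows_per_condition: int = 4,
    rng: np.random.Generator | None = None,
) -> list[SampleMatrix]:
    """Cheap dummy samples covering a full factorial design.

    The grids carry no class signal; these exist for count/partition
    arithmetic, not for training.
    """
    rng = rng or np.random.default_rng(0)
    out = []
    for plant in plants:
        for pos in positions:
            for conc in concentrations:
                for w in range(windows_per_condition):
                    out.append(
                        SampleMatrix(
                            grid=rng.random((30, 30)),
                            label_mM=conc,
                            plant_id=plant,
                            position=pos,
                            window_index=w,
                        )
                    )
    return out


@pytest.fixture(scope="session")
def fake_screening_samples() -> list[SampleMatrix]:
    return make_fake_samples()


@pytest.fixture(scope="session")
def fake_five_gradient_samples() -> list[SampleMatrix]:
    return make_fake_samples(
        positions=[TOP_BASAL], concentrations=CONCENTRATIONS_MM,
        windows_per_condition=10,
    )
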