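import numpy as np
import pytest

from mihcquant.phenotyping import default_panel
from mihcquant.simulate import SimConfig, generate_cohort, generate_worked_roi
from mihcquant.types import Cell


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def worked_roi():
    return generate_worked_roi()


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort (4 patients/group, 1 ROI each, ~350 cells/ROI)."""
    cfg = SimConfig(
        n_patients_per_group=4,
        rois_per_patient=1,
        tumor_density=150 / 651000.0,
        immune_density=150 / 651000.0,
        other_density=50 / 651000.0,
        seed=11,
    )
    return generate_cohort(cfg)


def random_cells(
    rng: np.random.Generator,
    n: int,
    markers,
    width: float = 930.0,
    height: float = 700.0,
    classes=("tumor", "immune", "other"),
    prefix: str = "c",
):
    """Uniform random cells with random marker intensities in {0..3}."""
    cells = []
    for i in range(n):
        cells.append(
            Cell(
                cell_id=f"{prefix}{i}",
                x=float(rng.random() * width),
                y=float(rng.random() * height),
                cell_class=classes[rng.integers(len(classes))],
                markers={m: int(rng.integers(0, 4)) for m in markers},
            )
        )
    return cells
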