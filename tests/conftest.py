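import dataclasses

import pytest

from ssfm import (
    NoiseModel,
    PhantomSpec,
    PreprocessConfig,
    class_by_label,
    default_calibration,
    default_class_table,
    default_grid,
    make_phantom,
    simulate_cube,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def classes():
    return default_class_table()


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture
def uniform_cube():
    """Factory: uniform single-class phantom cube + ground truth + labels."""

    def _make(
        label,
        seed=0,
        noise=NoiseModel(),
        m=60,
        n=30,
        spread_nm=None,
        center_nm=None,
    ):
        table = default_class_table()
        if spread_nm is not None or center_nm is not None:
            by_label = class_by_label(table)
            params = by_label[label]
            updates = {}
            if spread_nm is not None:
                updates["spread_nm"] = spread_nm
            if center_nm is not None:
                updates["center_nm"] = center_nm
            by_label[label] = dataclasses.replace(params, **updates)
            table = list(by_label.values())
        labels = make_phantom(PhantomSpec(m=m, n=n, background=label))
        cube, truth = simulate_cube(labels, table, noise=noise, seed=seed)
        return cube, truth, labels

    return _make


@pytest.fixture
def sharp_cfg():
    """Preprocess config with smoothing off: exact noise-free recovery."""
    return PreprocessConfig(smooth_sigma_nm=0.0)
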