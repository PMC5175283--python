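import numpy as np
import pytest

import msiquant as mq


def as_norm(values, mask=None, pixel_size_um=100.0):
    """Wrap a plain array as a NormalizedImage for metric-level tests."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return mq.NormalizedImage(values, np.asarray(mask, bool), istd_floor=1e-9,
                              pixel_size_um=pixel_size_um)


@pytest.fixture(scope="session")
def threshold_model():
    """k=3 background threshold pooled from two untreated control phantoms."""
    controls = [mq.normalize(*mq.make_control_section(seed=s))
                for s in (101, 102)]
    return mq.estimate_threshold(controls, k=3.0)


@pytest.fixture(scope="session")
def calibration_curve():
    """Calibration curve from one normalized spotted dilution series."""
    drug, istd, spots = mq.make_calibration_section(seed=7)
    return mq.build_calibration(spots, mq.normalize(drug, istd))


@pytest.fixture
def identity_curve():
    """y = x curve for tests that need signal == amount."""
    return mq.CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0,
                               points=[(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)],
                               amount_range=(0.0, 1e9))
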