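import numpy as np
import pytest

from stalksect import PipelineConfig, analyze_section, feret_diameters
from stalksect.phantoms import make_phantom, make_recovery_sweep, maize_like_spec, wheat_like_spec


@pytest.fixture(scope="session")
def maize_phantom():
    spec = maize_like_spec()
    img, truth = make_phantom(spec, 42)
    return spec, img, truth


@pytest.fixture(scope="session")
def wheat_phantom():
    spec = wheat_like_spec()
    img, truth = make_phantom(spec, 7)
    return spec, img, truth


@pytest.fixture(scope="session")
def recovery_sweep():
    """50 analyzed phantoms spanning 2-20 mm diameters, both plant types."""
    sweep = make_recovery_sweep(50, seed=123)
    results = []
    for spec, img, truth in sweep:
        config = PipelineConfig(plant_type=spec.plant_type, px_per_mm=spec.px_per_mm)
        record, artifacts = analyze_section(img, config)
        feret = feret_diameters(artifacts["boundaries"], img.calibration)
        results.append((spec, truth, record, feret, artifacts))
    return results


def disk_mask(shape_hw, center_xy, radius):
    """Independent raster-disk helper used by oracle tests."""
    h, w = shape_hw
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2
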