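import numpy as np
import pytest

import vesselmetrics as vm

PITCH = 3.0 / 304


@pytest.fixture(scope="session")
def pitch():
    return PITCH


@pytest.fixture(scope="session")
def semicircle_spec():
    """Semicircle of radius 0.5 mm, width 0.05 mm, centered in the field."""
    return vm.CenterlineSpec(
        "circular_arc",
        {"center": (0.0, 0.0), "radius": 0.5, "angle_start": 0.0, "angle_span": np.pi},
        width_mm=0.05,
        n_samples=101,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Six-eye, three-group phantom cohort shared by the slower tests."""
    return vm.generate_cohort(vm.CohortSpec(eyes_per_group=2, seed=11))


def random_phantom(rng: np.random.Generator, shape=(128, 128), pitch_mm=3.0 / 128):
    """One random multi-curve label map for oracle-equivalence checks."""
    half = shape[0] * pitch_mm / 2 * 0.8
    specs = []
    for _ in range(rng.integers(2, 5)):
        kind = rng.choice(["line", "circular_arc", "sinusoid"])
        cls = rng.choice(["artery", "vein"])
        width = rng.uniform(3.2, 6.0) * pitch_mm
        if kind == "line":
            params = {"p0": rng.uniform(-half, half, 2), "p1": rng.uniform(-half, half, 2)}
            if np.hypot(*(params["p1"] - params["p0"])) < 0.3:
                continue
        elif kind == "circular_arc":
            params = {
                "center": rng.uniform(-half / 2, half / 2, 2),
                "radius": rng.uniform(0.3, half),
                "angle_start": rng.uniform(0, 2 * np.pi),
                "angle_span": rng.uniform(0.8, np.pi),
            }
        else:
            params = {
                "p0": rng.uniform(-half, half, 2),
                "p1": rng.uniform(-half, half, 2),
                "amplitude": rng.uniform(0.0, 0.1),
                "frequency": rng.uniform(0.5, 2.5),
            }
            if np.hypot(*(params["p1"] - params["p0"])) < 0.3:
                continue
        specs.append(
            vm.CenterlineSpec(kind, params, width_mm=width, vessel_class=cls, n_samples=64)
        )
    if not specs:
        specs = [
            vm.CenterlineSpec(
                "line",
                {"p0": (-half, 0.0), "p1": (half, 0.0)},
                width_mm=4 * pitch_mm,
                n_samples=64,
            )
        ]
    lmap, _ = vm.rasterize(specs, shape, pitch_mm)
    return lmap
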