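import flapmon as fm
import numpy as np
import pytest


@pytest.fixture(scope="session")
def cohort65():
    """Baseline-sized cohort with exact published margins."""
    return fm.simulate_cohort(fm.default_generator_config(seed=7))


@pytest.fixture(scope="session")
def cohort500():
    """Large cohort at the default calibration for parameter-recovery checks."""
    return fm.simulate_cohort(
        fm.default_generator_config(n_flaps=500, seed=11, replicate_table2=False)
    )


@pytest.fixture(scope="session")
def cohort500_t4():
    """Large cohort with the first-interval (t4) calibration entries enabled."""
    return fm.simulate_cohort(
        fm.default_generator_config(
            n_flaps=500, seed=11, replicate_table2=False, include_t4_calibration=True
        )
    )


@pytest.fixture(scope="session")
def deltas500(cohort500):
    return fm.compute_deltas(cohort500.hsi)


@pytest.fixture(scope="session")
def detections500(cohort500):
    return fm.detect_cohort(cohort500)


@pytest.fixture(scope="session")
def detections65(cohort65):
    return fm.detect_cohort(cohort65)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Even-odd ray-casting point-in-polygon test, scalar and loop-based."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def first_true_time(pairs) -> float | None:
    """Linear-scan oracle: earliest timestamp whose flag is true."""
    best = None
    for t, flag in pairs:
        if flag and (best is None or t < best):
            best = t
    return best


def star_polygon(rng: np.random.Generator, center, n_vertices: int, radius: float):
    """A random simple polygon for oracle-equivalence tests (redrawn until valid)."""
    from shapely.geometry import Polygon

    cx, cy = center
    for _ in range(100):
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
        radii = rng.uniform(0.3 * radius, radius, n_vertices)
        verts = np.column_stack((cx + radii * np.cos(angles), cy + radii * np.sin(angles)))
        if Polygon(verts).is_valid:
            return verts
    raise RuntimeError("could not draw a valid polygon")
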