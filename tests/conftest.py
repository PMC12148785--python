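import numpy as np
import pytest

from planwatch import rtio, synthgen
from planwatch.cli import demo_phantom_spec

Z_SLAB = (1.0, 13.0)


def half_box_spec(seed: int = 3) -> synthgen.PhantomSpec:
    """Structure straddling a 10 Gy / 0 Gy boundary: V(5 Gy) = 50% exactly."""
    return synthgen.PhantomSpec(
        shape=(10, 20, 20),
        spacing=(2.0, 2.0, 2.0),
        origin=(0.0, 0.0, 0.0),
        regions=[(((-1.0, 19.0), (-1.0, 39.0), Z_SLAB), 10.0)],
        structures=[("half_box_dx", ((9.0, 29.0), (5.0, 21.0), Z_SLAB))],
        metrics=["V5Gy[%]", "Dmean[Gy]", "Dmax[Gy]"],
        seed=seed,
    )


def two_level_spec(seed: int = 4) -> synthgen.PhantomSpec:
    """Half the structure at 10 Gy, half at 2 Gy: Dmean = 6 Gy exactly."""
    return synthgen.PhantomSpec(
        shape=(10, 20, 20),
        spacing=(2.0, 2.0, 2.0),
        origin=(0.0, 0.0, 0.0),
        regions=[
            (((-1.0, 19.0), (-1.0, 39.0), Z_SLAB), 10.0),
            (((19.0, 39.0), (-1.0, 39.0), Z_SLAB), 2.0),
        ],
        structures=[("two_level_dx", ((9.0, 29.0), (5.0, 21.0), Z_SLAB))],
        metrics=["Dmean[Gy]", "V5Gy[%]", "D50%[Gy]"],
        seed=seed,
    )


@pytest.fixture(scope="session")
def demo_spec():
    return demo_phantom_spec(seed=7)


@pytest.fixture(scope="session")
def phantom_paths(tmp_path_factory, demo_spec):
    out = tmp_path_factory.mktemp("phantom")
    return synthgen.make_phantom(demo_spec, str(out))


@pytest.fixture(scope="session")
def phantom(phantom_paths):
    grid = rtio.read_rtdose(phantom_paths["rtdose"])
    structures = rtio.read_rtstruct(phantom_paths["rtstruct"])
    plan = rtio.read_rtplan(phantom_paths["rtplan"])
    return grid, structures, plan


def brute_force_volume(grid, structure, dose_threshold=None):
    """Independent DVH oracle: voxel-center membership by ray-casting.

    Returns (member voxel doses, fraction >= dose_threshold or None).
    Implements even-odd crossing counting from scratch (no shapely /
    matplotlib) so it cannot share a bug with the production path.
    """

    def point_in_poly(x, y, poly):
        inside = False
        n = len(poly)
        for i in range(n):
            x1, y1 = poly[i]
            x2, y2 = poly[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x < x_cross:
                    inside = not inside
        return inside

    planes = structure.planes()
    plane_zs = sorted(planes)
    nz, ny, nx = grid.values.shape
    dx, dy, dz = grid.spacing
    x0, y0, z0 = grid.origin
    doses = []
    for k in range(nz):
        z = z0 + k * dz
        zp = min(plane_zs, key=lambda p: abs(p - z))
        if abs(z - zp) > dz / 2 + 1e-9:
            continue
        polys = planes[zp]
        for j in range(ny):
            y = y0 + j * dy
            for i in range(nx):
                x = x0 + i * dx
                crossings = sum(point_in_poly(x, y, p) for p in polys)
                if crossings % 2 == 1:
                    doses.append(grid.values[k, j, i])
    doses = np.array(doses)
    frac = None
    if dose_threshold is not None and len(doses):
        frac = float(np.mean(doses >= dose_threshold))
    return doses, frac
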