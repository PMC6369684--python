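import numpy as np
import pytest

from gp_atlas import synthetic as syn


@pytest.fixture(scope="session")
def reference_shell():
    """The default labeled reference shell (expensive; built once)."""
    return syn.make_reference_shell()


@pytest.fixture(scope="session")
def revolution_shell():
    """Sphere + cylinder + exact torus fillet, with analytic curvatures."""
    return syn.make_sphere_cylinder_shell()


@pytest.fixture(scope="session")
def sphere_mesh():
    """A small unlabeled icosphere-style mesh for atlas/geometry tests."""
    return _make_sphere(radius=20.0, n=24)


def _make_sphere(radius: float, n: int):
    """Lat-long sphere triangulation (poles fanned)."""
    from gp_atlas.surface import AtrialSurface

    thetas = np.linspace(0, np.pi, n)[1:-1]
    phis = 2 * np.pi * np.arange(2 * n) / (2 * n)
    verts = [np.array([0.0, 0.0, radius])]
    for th in thetas:
        for ph in phis:
            verts.append(
                radius
                * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
            )
    verts.append(np.array([0.0, 0.0, -radius]))
    verts = np.vstack(verts)
    m = len(phis)
    faces = []
    for j in range(m):
        faces.append([0, 1 + j, 1 + (j + 1) % m])
    for i in range(len(thetas) - 1):
        a0, a1 = 1 + i * m, 1 + (i + 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([a0 + j, a1 + j, a1 + jn])
            faces.append([a0 + j, a1 + jn, a0 + jn])
    south = len(verts) - 1
    b0 = 1 + (len(thetas) - 1) * m
    for j in range(m):
        faces.append([south, b0 + (j + 1) % m, b0 + j])
    labels = np.full(len(verts), "BODY", dtype="U8")
    return AtrialSurface(
        vertices=verts, faces=np.array(faces, int), labels=labels, surface_id="sphere"
    )


def make_random_series(rng, n_pre=12, hfs_ms=10_000.0, lo=300.0, hi=1500.0):
    """A random but structurally valid BeatSeries."""
    from gp_atlas.beats import BeatSeries

    pre = np.concatenate([[0.0], np.cumsum(rng.uniform(lo, hi, size=n_pre))])
    hfs_start = pre[-1] + rng.uniform(10.0, 500.0)
    hfs_end = hfs_start + hfs_ms
    t = hfs_start + rng.uniform(0.0, 1200.0)
    times = list(pre)
    while t < hfs_end + rng.uniform(100.0, 2000.0):
        times.append(t)
        t += rng.uniform(lo, 3 * hi)
    times.append(t)
    return BeatSeries(r_times=np.array(times), hfs_start=hfs_start, hfs_end=hfs_end)
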