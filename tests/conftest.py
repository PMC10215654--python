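import numpy as np
import pytest

import insituplan as ip


def grid_plane(z: float = 0.0, size: float = 100.0, n: int = 21,
               origin=(0.0, 0.0)) -> ip.TriMesh:
    """Flat triangulated plane patch at height z (convenience substrate)."""
    xs = np.linspace(origin[0], origin[0] + size, n)
    ys = np.linspace(origin[1], origin[1] + size, n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return ip.TriMesh(verts, np.asarray(faces))


def rotz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ground-truth planning->robot transform used across the synthetic workflow:
# patient rotated 15 deg about the vertical and shifted into the arm workspace
GROUND_TRUTH = ip.RigidTransform(rotz(15.0), np.array([290.0, 50.0, 40.0]))


@pytest.fixture(scope="session")
def plane_mesh():
    return grid_plane(z=5.0, size=100.0, n=21)


@pytest.fixture(scope="session")
def sphere_mesh():
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=5, radius=50.0)
    return ip.TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def phantom_default():
    """Default-condition phantom: (spec, mesh, footprint, fiducials, patch)."""
    spec = ip.PhantomSpec()
    mesh, footprint, fiducials = ip.make_phantom(spec)
    patch = ip.extract_patch(mesh, footprint)
    return spec, mesh, footprint, fiducials, patch


@pytest.fixture(scope="session")
def phantom_coarse():
    """Coarser phantom for tests that do not assert sub-millimetre geometry."""
    spec = ip.PhantomSpec(chord_tol=5e-3, outer_resolution=4.0)
    mesh, footprint, fiducials = ip.make_phantom(spec)
    patch = ip.extract_patch(mesh, footprint)
    return spec, mesh, footprint, fiducials, patch


@pytest.fixture(scope="session")
def chain():
    return ip.default_chain()


@pytest.fixture(scope="session")
def sliced_default(phantom_default):
    """Default-settings conformal toolpath over the default phantom."""
    _, _, footprint, _, patch = phantom_default
    return ip.conformal_slice(patch, footprint, ip.SliceSettings())


@pytest.fixture(scope="session")
def executed_pipeline(phantom_default, sliced_default, chain):
    """Registered path + IK joint solutions for the zero-noise full loop."""
    _, _, _, fiducials, _ = phantom_default
    robot_fid = ip.robot_frame_fiducials(fiducials, GROUND_TRUTH)
    reg = ip.estimate_rigid(fiducials, robot_fid)
    registered = ip.transform_toolpath(sliced_default, reg.transform)
    joints = ip.joints_for_toolpath(chain, registered)
    return registered, joints
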