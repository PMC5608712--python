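import numpy as np
import pytest

from vasoelast.phantom import IntimaSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def homog_phantom():
    """Homogeneous 18 kPa wall at mouse-carotid scale (coarse mesh)."""
    spec = PhantomSpec(region_moduli={"wall": 18.0}, mesh_density=0.03)
    mesh, mat = make_phantom(spec)
    return spec, mesh, mat


@pytest.fixture(scope="session")
def two_region_phantom():
    """Concentric stiff intima (54 kPa) over an 18 kPa media."""
    spec = PhantomSpec(
        intima_spec=IntimaSpec(angular_extent_deg=360, max_thickness_mm=0.05),
        region_moduli={"intima": 54.0, "media": 18.0},
        mesh_density=0.02,
    )
    mesh, mat = make_phantom(spec)
    return spec, mesh, mat


@pytest.fixture(scope="session")
def speckle_frames():
    """Uniform speckle block and its rigid-shift variants (shared RF fixtures)."""
    from vasoelast.phantom import ScattererSet
    from vasoelast.rf import FrameGeometry, simulate_rf

    rng = np.random.default_rng(7)
    pos = rng.uniform(-0.35, 0.35, (2000, 2))
    amp = rng.normal(0.0, 1.0, 2000)
    geom = FrameGeometry.covering((-350, 350), (-350, 350))
    dz = geom.axial_step_um
    pre = simulate_rf(ScattererSet(pos, amp), geom)
    post_int = simulate_rf(ScattererSet(pos + [2 * dz * 1e-3, 0.0], amp), geom)
    post_sub = simulate_rf(ScattererSet(pos + [0.25 * dz * 1e-3, 0.0], amp), geom)
    return {"geom": geom, "pos": pos, "amp": amp, "pre": pre,
            "post_int": post_int, "post_sub": post_sub}
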