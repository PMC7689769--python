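import pytest

import halbachmri as hm
from halbachmri import gradientdesign as gd

# shared target region for coil design (18-cm sphere inside the 0.125 m former)
TARGET_DIAMETER = 0.18


@pytest.fixture(scope="session")
def dsv20():
    """20-cm DSV with a light (5 x 40 + 1) sampling for fast tests."""
    return hm.DSVRegion.fibonacci(diameter=0.20, n_shells=5, points_per_shell=40)


@pytest.fixture(scope="session")
def coil_target():
    return hm.DSVRegion.fibonacci(
        diameter=TARGET_DIAMETER, n_shells=6, points_per_shell=60
    )


@pytest.fixture(scope="session")
def former():
    return hm.CylindricalFormer()


@pytest.fixture(scope="session")
def y_coil(former, coil_target):
    return gd.design_gradient_coil("y", former, 1.0, coil_target)


@pytest.fixture(scope="session")
def z_coil(former, coil_target):
    return gd.design_gradient_coil("z", former, 1.0, coil_target)


@pytest.fixture(scope="session")
def x_coil(former, coil_target):
    return gd.design_gradient_coil("x", former, 1.0, coil_target)


@pytest.fixture(scope="session")
def x_coil_short():
    """x coil on a ~1:1 length-to-diameter former: strongly nonlinear."""
    short = hm.CylindricalFormer(radius=0.125, length=0.25)
    target = hm.DSVRegion.fibonacci(diameter=0.18, n_shells=6, points_per_shell=60)
    sf = gd.design_stream_function("x", short, 1.0, target)
    wires = gd.contour_wires(sf, 12, max_segment=0.006)
    g0 = gd._central_gradient(wires, "x")
    if g0 < 0:
        wires = wires.scaled(-wires.current)
    return wires


@pytest.fixture(scope="session")
def single_ring_elements():
    ring = hm.RingSpec(
        axial_position=0.0, layer_radii=(0.18, 0.193), magnets_per_layer=(16, 16)
    )
    design = hm.HalbachMagnetDesign(rings=(ring,), length=0.0)
    return hm.build_halbach_elements(design)
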