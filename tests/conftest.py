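import pytest

from saxsbeam import BeamGeometry, MediumProperties
from saxsbeam.phantoms import (
    EllipseZone,
    PhantomSpec,
    RectZone,
    make_embedded_disk_mask,
)


@pytest.fixture
def medium() -> MediumProperties:
    """Reference medium: grey/white matter attenuation with amyloid target."""
    return MediumProperties(mu=0.30, rho_t=5.5e5, sigma=5e-23)


@pytest.fixture
def beam() -> BeamGeometry:
    """60 keV beam, 20 cm mean target-to-detector distance."""
    return BeamGeometry.from_energy(60.0, L0=20.0)


@pytest.fixture
def slab_disk_spec() -> PhantomSpec:
    """Rectangular slab object with a single off-centre disk target.

    A slab gives every parallel path the same attenuation length, so the
    figure of merit compares target geometry alone across one orientation.
    """
    return PhantomSpec(
        grid=(220, 260),
        pixel_size=0.05,
        name="slab-disk",
        head=RectZone(center=(5.5, 6.5), half_sizes=(4.5, 5.5)),
        lobes=(EllipseZone(center=(4.0, 8.5), semi_axes=(1.5, 1.5)),),
    )


@pytest.fixture
def slab_disk_mask(slab_disk_spec):
    return make_embedded_disk_mask(slab_disk_spec)
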