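import numpy as np
import pytest

import tomomatch as tm


@pytest.fixture(scope="session")
def blob_template() -> tm.DensityVolume:
    """Asymmetric multi-lump density in a 16^3 box at 14 A voxels."""
    return tm.make_blob_template(box_size=16, voxel_size=14.0, seed=7)


@pytest.fixture(scope="session")
def blob_mask(blob_template) -> tm.MaskVolume:
    """Soft spherical mask covering the blob template."""
    return tm.build_spherical_mask(16, 160.0, 14.0, soft_edge_sigma=1.0)


@pytest.fixture(scope="session")
def small_phantom(blob_template):
    """64^3 phantom with 6 planted particles at SNR 1, 39/39 wedge."""
    spec = tm.PhantomSpec(
        template=blob_template,
        box=(64, 64, 64),
        n_particles=6,
        min_separation=250.0,
        snr=1.0,
        wedge=tm.WedgeSpec(39.0, 39.0),
        seed=3,
    )
    return tm.generate_phantom(spec)


@pytest.fixture(scope="session")
def random_particles() -> tm.ParticleList:
    """Seeded list of particles with random positions/orientations/scores."""
    rng = np.random.default_rng(21)
    orientations = tm.random_rotations(40, rng)
    particles = [
        tm.ParticleAnnotation(
            tomogram_id="tomo_1",
            position=tuple(float(v) for v in rng.uniform(10, 110, 3)),
            orientation=ori,
            score=float(rng.uniform(-0.2, 0.8)),
        )
        for ori in orientations
    ]
    return tm.ParticleList(particles, tomogram_dims=(128, 128, 128), voxel_size=13.8)
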