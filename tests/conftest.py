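import numpy as np
import pytest

from sgddm import (
    SimulationConfig,
    generate_movie,
    sg_structure_function,
    structure_function,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_movie():
    """Short anisotropic movie for cheap integration tests: paper-like pixel
    size and frame rate, reduced field and duration."""
    cfg = SimulationConfig(
        n_particles=12,
        n_frames=300,
        image_shape=(128, 128),
        D_T=0.24,
        D_R=0.30,
        seed=7,
    )
    seq, traj = generate_movie(cfg)
    return cfg, seq, traj


@pytest.fixture(scope="session")
def validation_tables():
    """Structure-function tables of replicate scaled-down 40x-like
    validation movies: 256x256 px at 0.1625 µm/px, 25 frames/s, 6000 frames,
    64 anisotropic particles each, ground truth set to the bright-field
    experiment's measured coefficients (D_T = 0.24 µm²/s, D_R = 0.30 s⁻¹).
    The rotational estimate at this field size carries ~15% per-movie
    statistical scatter (few Fourier modes per low-q annulus), so the
    package's measurement protocol averages independent replicates; three
    are generated here.  Only the tables are kept so each movie's memory is
    released before the next is rendered."""
    cfg = SimulationConfig(
        n_particles=64,
        n_frames=6000,
        image_shape=(256, 256),
        D_T=0.24,
        D_R=0.30,
        seed=101,
    )
    tables = []
    for seed in (101, 102, 103):
        import dataclasses

        rep = dataclasses.replace(cfg, seed=seed)
        seq, _ = generate_movie(rep)
        ddm_table = structure_function(seq, max_pairs=600, q_max=8.0)
        sg_table = sg_structure_function(seq, max_pairs=600, q_max=8.0)
        del seq
        tables.append((ddm_table, sg_table))
    return cfg, tables


@pytest.fixture(scope="session")
def tracking_movie():
    """Sparse tracking-validation movie: same optics, frame rate and
    ground-truth coefficients as the validation movie, but at a particle
    density where single-particle images do not overlap (the validity
    precondition of the SPT estimators)."""
    cfg = SimulationConfig(
        n_particles=64,
        n_frames=1250,
        image_shape=(512, 512),
        D_T=0.24,
        D_R=0.30,
        seed=202,
    )
    seq, traj = generate_movie(cfg)
    return cfg, seq, traj
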