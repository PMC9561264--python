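import numpy as np
import pandas as pd
import pytest

from afm_dnacomplex import GeneratorConfig, generate_scene
from afm_dnacomplex.chains import ChainConformation
from afm_dnacomplex.synthetic import render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def straight_chain(n_bp: int = 506, rise: float = 0.34,
                   angle_deg: float = 0.0) -> ChainConformation:
    """A straight chain at a given orientation (for rod/kink scenes)."""
    t = np.deg2rad(angle_deg)
    s = np.arange(n_bp) * rise
    nodes = np.column_stack((s * np.cos(t), s * np.sin(t)))
    return ChainConformation(nodes, rise)


def one_complex_frame(position_fraction: float, volume: float = 100.0,
                      angle: float = 0.0, is_qd: bool = False,
                      molecule_id: int = 0) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": molecule_id, "kind": "specific",
        "position_fraction": position_fraction, "bend_angle_true": angle,
        "bend_direction": 1.0, "volume_true": volume, "is_qd": is_qd,
    }])


def no_complexes() -> pd.DataFrame:
    return one_complex_frame(0.5).iloc[:0]


@pytest.fixture(scope="session")
def rod_scene():
    """One straight 171.7 nm rod, noiseless."""
    cfg = GeneratorConfig(n_molecules=1, noise_sd_nm=0.0)
    return render_scene([straight_chain()], no_complexes(), cfg,
                        np.random.default_rng(0))


@pytest.fixture(scope="session")
def bare_dna_scene():
    """16 bare WLC molecules with default imaging noise."""
    cfg = GeneratorConfig(n_molecules=16, occupancy_specific=0.0,
                          nonspecific_rate=0.0, seed=8)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def bent35_scene():
    """30 molecules, each with one specific complex in the 35 deg state."""
    cfg = GeneratorConfig(n_molecules=30, occupancy_specific=1.0,
                          nonspecific_rate=0.0, bend_state_means=(35.0,),
                          bend_state_weights=(1.0,), bend_state_sd=8.0,
                          seed=7)
    return generate_scene(cfg)
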