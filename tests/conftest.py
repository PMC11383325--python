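"""Shared fixtures: toy structures, factor-model ensembles, tiny PDB files."""

import numpy as np
import pytest

import ensemblekit as ek


@pytest.fixture(scope="session")
def helix_ca_50():
    return ek.make_toy_structure(50, "ideal-helix")


@pytest.fixture(scope="session")
def helix_backbone_12():
    return ek.make_toy_structure(12, "ideal-helix", with_backbone=True,
                                 with_polar_hydrogens=True)


@pytest.fixture(scope="session")
def chain_backbone_5():
    """5-residue poly-alanine backbone (N, CA, C, O), no hydrogens."""
    return ek.make_toy_structure(5, "extended", with_backbone=True)


@pytest.fixture(scope="session")
def chain_ca_5():
    return ek.make_toy_structure(5, "extended")


def two_domain_spec(n_frames=500, seed=7, **kwargs):
    """The documented anticorrelated two-domain factor model (50 residues)."""
    defaults = dict(
        residues_per_domain=(25, 25),
        factor_correlation=np.array([[1.0, -0.8], [-0.8, 1.0]]),
        n_frames=n_frames,
        seed=seed,
    )
    defaults.update(kwargs)
    return ek.FactorModelSpec(**defaults)


@pytest.fixture(scope="session")
def make_two_domain_spec():
    return two_domain_spec


@pytest.fixture(scope="session")
def small_planted_ensemble(helix_ca_50):
    """500-frame anticorrelated two-domain ensemble on the Cα helix."""
    spec = two_domain_spec(n_frames=500, seed=7)
    traj, truth = ek.sample_ensemble(spec, helix_ca_50)
    return spec, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
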