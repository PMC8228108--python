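import numpy as np
import pytest

from lcpkit.ensemble import ConformationEnsemble


def straight_chain(n_residues: int, n_frames: int = 1, spacing: float = 3.8,
                   first_id: int = 1) -> ConformationEnsemble:
    """Collinear Cα chain along x with constant spacing, identical frames."""
    coords = np.zeros((n_frames, n_residues, 3))
    coords[:, :, 0] = np.arange(n_residues) * spacing
    return ConformationEnsemble(
        residue_ids=np.arange(first_id, first_id + n_residues),
        sequence="A" * n_residues,
        coords=coords,
    )


def random_ensemble(n_frames: int, n_residues: int, seed: int = 0,
                    scale: float = 30.0) -> ConformationEnsemble:
    """Unstructured random-coordinate ensemble (no chain geometry)."""
    rng = np.random.default_rng(seed)
    return ConformationEnsemble(
        residue_ids=np.arange(1, n_residues + 1),
        sequence="G" * n_residues,
        coords=rng.uniform(-scale, scale, size=(n_frames, n_residues, 3)),
    )


@pytest.fixture
def straight75():
    return straight_chain(100, n_frames=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
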