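"""Shared fixtures: synthetic rungs, filaments and ThT curves.

All fixtures are generated programmatically; no coordinate or plate
files are shipped.  Deposited-model comparisons look for files under
``data/depositions/`` at the repository root (see tests that use
``depositions_dir``).
"""

from pathlib import Path

import numpy as np
import pytest

from fibrilfold import (
    FoldStructure,
    HelicalParams,
    Residue,
    ResidueChain,
    build_filament,
    crossover_to_twist,
    make_serpentine_rung,
)

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def depositions_dir() -> Path:
    return REPO_ROOT / "data" / "depositions"


@pytest.fixture
def rung() -> ResidueChain:
    """Default 100-residue serpentine rung, tau-like numbering from 273."""
    return make_serpentine_rung()


@pytest.fixture
def small_rung() -> ResidueChain:
    """Short rung for brute-force oracle comparisons (<= 30 residues)."""
    return make_serpentine_rung(n_residues=24, start_res=1, strand_len=8)


@pytest.fixture
def type1_params() -> HelicalParams:
    """4.8 Å rise with the ~600 Å crossover (left-handed)."""
    return HelicalParams(4.8, crossover_to_twist(600.0, 4.8, "left"))


@pytest.fixture
def type2_params() -> HelicalParams:
    """4.8 Å rise with the ~750 Å crossover (left-handed)."""
    return HelicalParams(4.8, crossover_to_twist(750.0, 4.8, "left"))


@pytest.fixture
def filament(rung, type1_params) -> FoldStructure:
    return build_filament(rung, type1_params, 5)


def make_chain(coords, start=1, chain_id="A", aa="A"):
    """Chain from an (n, 3) CA coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = [
        Residue(start + i, aa, {"CA": coords[i]}) for i in range(len(coords))
    ]
    return ResidueChain(chain_id, residues)


def random_chain(rng, n, start=1, chain_id="A", scale=10.0):
    """Random CA-only chain for property tests."""
    return make_chain(rng.normal(0.0, scale, size=(n, 3)), start=start, chain_id=chain_id)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
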