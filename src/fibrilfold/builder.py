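"""Idealized helical filament fixtures.

Amyloid filaments are helical stacks: rung *k* is rung 0 rotated by
``k * twist`` about the helical axis and translated by ``k * rise``
along it.  The cross-beta rise is ~4.8 Å per rung, and the *crossover
distance* — the axial length over which the ribbon rotates 180° — ties
rise and twist together:

    crossover = 180 deg * rise / |twist|

Tau filaments are left-handed (negative twist by convention).  The
builders here create exact rigid stacks from a single rung (optionally
with seeded coordinate noise), apply smooth localized deformations for
ground-truth localization tests, and recover rise/twist/crossover from
coordinates for round-trip validation.  Fixtures are geometric, not
stereochemical: bond lengths and angles are not modelled.
"""

from __future__ import annotations

import itertools
import json
import string
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .rmsd import kabsch_superpose
from .structure import FoldStructure, Residue, ResidueChain

CROSS_BETA_RISE = 4.8  # Å per rung, canonical cross-beta spacing


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry of a filament: rise (Å/rung) and signed twist (deg/rung).

    Negative twist = left-handed (the tau convention).  ``crossover`` is
    the derived half-turn distance in Å.
    """

    rise: float
    twist: float

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if self.twist == 0:
            raise ValueError("twist must be nonzero (crossover would be infinite)")

    @property
    def crossover(self) -> float:
        return 180.0 * self.rise / abs(self.twist)

    @property
    def handedness(self) -> str:
        return "left" if self.twist < 0 else "right"


def crossover_to_twist(
    crossover: float, rise: float, handedness: str = "left"
) -> float:
    """Twist per rung (degrees, signed) from crossover distance and rise.

    A crossover is half a helical turn, so |twist| = 180 * rise / crossover;
    left handedness gives the negative sign.
    """
    if crossover <= 0 or rise <= 0:
        raise ValueError("crossover and rise must be positive")
    if handedness not in ("left", "right"):
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    twist = 180.0 * rise / crossover
    return -twist if handedness == "left" else twist


def _chain_labels(n: int) -> list[str]:
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n <= len(alphabet):
        return list(alphabet[:n])
    return [f"{a}{b}" for a, b in itertools.product(alphabet, repeat=2)][:n]


def build_filament(
    rung: ResidueChain,
    params: HelicalParams,
    n_rungs: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FoldStructure:
    """Stack ``n_rungs`` rigid copies of ``rung`` with the given symmetry.

    Rung k is the input rotated by k*twist about the vertical axis
    through the rung's CA centroid and translated by k*rise along z, so
    the helical axis is the z axis by construction.  Chains are labelled
    consecutively (A, B, ...).  ``noise_sd`` adds seeded isotropic
    Gaussian jitter per atom (default off; rungs are then exact copies).
    """
    if n_rungs < 1:
        raise ValueError("n_rungs must be >= 1")
    centroid = rung.ca_coords().mean(axis=0)
    pivot = np.array([centroid[0], centroid[1], 0.0])
    rng = np.random.default_rng(seed)
    labels = _chain_labels(n_rungs)
    chains = []
    for k in range(n_rungs):
        rot = Rotation.from_euler("z", k * params.twist, degrees=True)
        shift = np.array([0.0, 0.0, k * params.rise])
        residues = []
        for res in rung.residues:
            atoms = {}
            for name, xyz in res.atoms.items():
                new = rot.apply(xyz - pivot) + pivot + shift
                if noise_sd > 0:
                    new = new + rng.normal(0.0, noise_sd, size=3)
                atoms[name] = new
            residues.append(Residue(res.number, res.aa, atoms))
        chains.append(ResidueChain(labels[k], residues))
    return FoldStructure(id=f"filament_{n_rungs}x", chains=chains)


def perturb_region(
    chain: ResidueChain,
    res_range: tuple[int, int],
    amplitude: float,
    seed: int | None = None,
) -> ResidueChain:
    """Displace a residue range by a smooth cosine-tapered bump.

    All residues with numbers in the closed ``res_range`` move along a
    single random unit direction (from the seeded generator) with a
    cosine taper that is zero at both range edges' neighbours and whose
    peak displacement equals ``amplitude`` exactly.  Residues outside
    the range are bit-identical to the input.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    lo, hi = res_range
    selected = [i for i, r in enumerate(chain.residues) if lo <= r.number <= hi]
    if not selected:
        warnings.warn(f"range {lo}-{hi} selects no residues; returning input unchanged")
        return chain
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    m = len(selected)
    raw = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(m) + 1) / (m + 1)))
    taper = raw / raw.max()  # peak displacement exactly = amplitude
    offsets = {idx: amplitude * w * direction for idx, w in zip(selected, taper)}
    residues = []
    for i, res in enumerate(chain.residues):
        if i in offsets:
            atoms = {name: xyz + offsets[i] for name, xyz in res.atoms.items()}
            residues.append(Residue(res.number, res.aa, atoms))
        else:
            residues.append(res)  # untouched residues share the input arrays
    return ResidueChain(chain.chain_id, residues)


def estimate_helical_params(structure: FoldStructure) -> HelicalParams:
    """Recover rise and signed twist from a multi-rung filament.

    Requires >= 2 rungs of identical residue composition.  The helical
    axis is the first principal component of all CA positions, oriented
    so the rise (mean axial centroid spacing between consecutive rungs)
    is positive.  Twist is the mean rotation angle of the optimal
    adjacent-rung superposition, signed by its sense about that axis.
    """
    chains = structure.chains
    if len(chains) < 2:
        raise ValueError("need >= 2 rungs to estimate helical parameters")
    numbers0 = chains[0].numbers
    for c in chains[1:]:
        if not np.array_equal(c.numbers, numbers0):
            raise ValueError("rungs differ in residue composition")
    from .structure import principal_axis

    axis = principal_axis(structure)
    centroids = np.array([c.ca_coords().mean(axis=0) for c in chains])
    spacings = np.diff(centroids @ axis)
    if spacings.mean() < 0:
        axis = -axis
        spacings = -spacings
    rise = float(spacings.mean())
    if rise <= 1e-9:
        raise ValueError("rungs are axially coincident; rise is not positive")
    angles = []
    for a, b in zip(chains, chains[1:]):
        R, _, _ = kabsch_superpose(b.ca_coords(), a.ca_coords())
        rotvec = Rotation.from_matrix(R).as_rotvec(degrees=True)
        angles.append(float(rotvec @ axis))
    twist = float(np.mean(angles))
    return HelicalParams(rise=rise, twist=twist)


def make_serpentine_rung(
    n_residues: int = 100,
    start_res: int = 273,
    strand_len: int = 20,
    ca_spacing: float = 3.8,
    strand_gap: float = CROSS_BETA_RISE,
    chain_id: str = "A",
) -> ResidueChain:
    """Default fixture rung: a planar serpentine CA trace.

    Residues run along antiparallel straight strands of ``strand_len``
    (CA-CA 3.8 Å) separated by the 4.8 Å cross-beta gap, mimicking the
    meandering cross-section of an amyloid protofilament rung in the
    z = 0 plane.  Numbering defaults to a tau-core-like span starting at
    273; identities cycle through the 20 standard amino acids.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    residues = []
    for k in range(n_residues):
        strand, pos = divmod(k, strand_len)
        x = pos if strand % 2 == 0 else strand_len - 1 - pos
        coords = np.array([x * ca_spacing, strand * strand_gap, 0.0])
        residues.append(
            Residue(start_res + k, alphabet[k % 20], {"CA": coords})
        )
    return ResidueChain(chain_id, residues)


def write_fixture_metadata(path, params: HelicalParams, n_rungs: int, **extra) -> None:
    """Sidecar JSON recording how a synthetic filament was generated."""
    payload = {
        "rise_A_per_rung": params.rise,
        "twist_deg_per_rung": params.twist,
        "handedness": params.handedness,
        "crossover_A": params.crossover,
        "n_rungs": n_rungs,
        "sign_convention": "negative twist = left-handed",
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
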