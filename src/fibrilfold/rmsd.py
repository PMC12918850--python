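"""Sliding-window superposed backbone RMSD between filament folds.

The comparison statistic is built from per-window optimal rigid
superposition: for every contiguous run of paired residues of length
``w >= min_window`` (windows never cross a correspondence segment
boundary), the window's backbone atoms are independently superposed by
the Kabsch algorithm and the residual RMSD recorded.  Fitting each
window on its own — rather than windowing residuals of one global fit —
is what lets locally conserved motifs score near zero even when their
relative orientation in the two folds differs by a large rotation.

The *localized RMSD* summary is the unweighted mean of all window
RMSDs; ranking a query fold against a fold library orders by this
scalar.  The full matrix is rendered as a triangular heat-map (window
start residue on x, window length on y).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import ResidueCorrespondence, correspond_by_numbering
from .structure import ResidueChain

DEFAULT_ATOM_SET = ("CA",)
DEFAULT_MIN_WINDOW = 3

#: named residue ranges (2N4R numbering) recurrent in tau fold comparisons
TAU_MOTIFS: dict[str, tuple[int, int]] = {
    "R3_hairpin": (312, 334),
    "cofactor_site": (290, 311),
    "R2_strand": (285, 304),
    "R4_C_strand": (354, 375),
}


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rigid superposition of paired point sets.

    Finds rotation ``R`` (det +1; reflections excluded so mirror-image
    folds never score as similar) and translation ``t`` minimizing
    ``|X - (Y @ R.T + t)|``, returning ``(R, t, rmsd)`` where rmsd is
    the global least-squares minimum over rigid motions.  Degenerate
    inputs (collinear or coincident points) still yield the optimal
    residual even though the rotation is then not unique.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"paired (n, 3) arrays required, got {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot superpose zero points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xc, Y - yc
    H = Yc.T @ Xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = xc - R @ yc
    diff = Xc - Yc @ R.T
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def _paired_coords(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    pairs: Sequence[tuple[int, int]],
    atom_set: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack coordinates of atoms (from atom_set) present in both residues."""
    xs, ys = [], []
    for i, j in pairs:
        ra, rb = chain_a.residues[i], chain_b.residues[j]
        for name in atom_set:
            if name in ra.atoms and name in rb.atoms:
                xs.append(ra.atoms[name])
                ys.append(rb.atoms[name])
    return np.array(xs), np.array(ys)


@dataclass
class WindowRMSDMatrix:
    """All-window superposed RMSDs for one fold pair.

    ``entries`` maps (start position in the correspondence, window
    length in residues) to RMSD in Å.  ``start_numbers_a`` maps each
    correspondence position to the chain-A residue number, for plotting
    and export.
    """

    id_a: str
    id_b: str
    entries: dict[tuple[int, int], float]
    min_window: int
    atom_set: tuple[str, ...]
    start_numbers_a: np.ndarray
    start_numbers_b: np.ndarray

    def __len__(self) -> int:
        return len(self.entries)

    def values(self) -> np.ndarray:
        return np.array(list(self.entries.values()))

    def to_tsv(self, path: str | Path) -> None:
        """Columns: start_res, end_res (chain A numbering), length, rmsd_A."""
        with open(path, "w") as fh:
            fh.write("start_res\tend_res\tlength\trmsd_A\n")
            for (start, length) in sorted(self.entries):
                s = self.start_numbers_a[start]
                e = self.start_numbers_a[start + length - 1]
                fh.write(f"{s}\t{e}\t{length}\t{self.entries[start, length]:.6f}\n")


def window_rmsd_matrix(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    corr: ResidueCorrespondence | None = None,
    min_window: int = DEFAULT_MIN_WINDOW,
    atom_set: Sequence[str] = DEFAULT_ATOM_SET,
) -> WindowRMSDMatrix:
    """RMSD of every admissible window under per-window superposition.

    Windows are contiguous runs inside single correspondence segments
    with length >= ``min_window`` (default 3, the smallest window with a
    non-trivial rigid fit).  If every segment is shorter than
    ``min_window`` the matrix is empty and a warning is issued.
    """
    if corr is None:
        corr = correspond_by_numbering(chain_a, chain_b)
    if min_window < 3:
        raise ValueError("min_window must be >= 3")
    entries: dict[tuple[int, int], float] = {}
    for seg_start, seg_stop in corr.segments:
        seg_len = seg_stop - seg_start
        for length in range(min_window, seg_len + 1):
            for start in range(seg_start, seg_stop - length + 1):
                window = corr.pairs[start : start + length]
                X, Y = _paired_coords(chain_a, chain_b, window, atom_set)
                _, _, rmsd = kabsch_superpose(X, Y)
                entries[(start, length)] = rmsd
    if not entries:
        warnings.warn(
            f"no segment reaches min_window={min_window}; matrix is empty",
            stacklevel=2,
        )
    return WindowRMSDMatrix(
        id_a=chain_a.chain_id,
        id_b=chain_b.chain_id,
        entries=entries,
        min_window=min_window,
        atom_set=tuple(atom_set),
        start_numbers_a=corr.numbers_a(),
        start_numbers_b=corr.numbers_b(),
    )


def localized_rmsd(matrix: WindowRMSDMatrix) -> float:
    """Unweighted arithmetic mean of all window RMSDs (Å)."""
    if not matrix.entries:
        raise ValueError("no admissible windows")
    return float(matrix.values().mean())


def region_rmsd(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    corr: ResidueCorrespondence | None = None,
    start_res: int = 0,
    end_res: int = 0,
    atom_set: Sequence[str] = DEFAULT_ATOM_SET,
) -> float:
    """Single-window superposed RMSD over the closed residue range.

    The range refers to chain-A residue numbers and must be fully paired
    in the correspondence; missing numbers are reported in the error.
    """
    if corr is None:
        corr = correspond_by_numbering(chain_a, chain_b)
    numbers = corr.numbers_a()
    wanted = set(range(start_res, end_res + 1))
    have = set(int(n) for n in numbers)
    missing = sorted(wanted - have)
    if missing:
        raise ValueError(
            f"residues not paired in range {start_res}-{end_res}: {missing}"
        )
    mask = [k for k, n in enumerate(numbers) if start_res <= n <= end_res]
    window = [corr.pairs[k] for k in mask]
    X, Y = _paired_coords(chain_a, chain_b, window, atom_set)
    _, _, rmsd = kabsch_superpose(X, Y)
    return rmsd


@dataclass
class FoldComparisonSummary:
    """Localized RMSD plus per-motif values for one fold pair."""

    id_a: str
    id_b: str
    localized_rmsd: float
    motif_rmsd: dict[str, float | None]
    matrix: WindowRMSDMatrix

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_a": self.id_a,
            "fold_b": self.id_b,
            "localized_rmsd_A": self.localized_rmsd,
            "motif_rmsd_A": self.motif_rmsd,
            "min_window": self.matrix.min_window,
            "atom_set": list(self.matrix.atom_set),
            "n_windows": len(self.matrix),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def compare_folds(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    corr: ResidueCorrespondence | None = None,
    min_window: int = DEFAULT_MIN_WINDOW,
    atom_set: Sequence[str] = DEFAULT_ATOM_SET,
    motifs: Mapping[str, tuple[int, int]] = TAU_MOTIFS,
) -> FoldComparisonSummary:
    """Full comparison: window matrix, localized RMSD, per-motif RMSDs.

    Motifs whose range is not fully paired are reported as ``None``.
    """
    if corr is None:
        corr = correspond_by_numbering(chain_a, chain_b)
    matrix = window_rmsd_matrix(chain_a, chain_b, corr, min_window, atom_set)
    motif_rmsd: dict[str, float | None] = {}
    for name, (lo, hi) in motifs.items():
        try:
            motif_rmsd[name] = region_rmsd(
                chain_a, chain_b, corr, lo, hi, atom_set=atom_set
            )
        except ValueError:
            motif_rmsd[name] = None
    return FoldComparisonSummary(
        id_a=chain_a.chain_id,
        id_b=chain_b.chain_id,
        localized_rmsd=localized_rmsd(matrix),
        motif_rmsd=motif_rmsd,
        matrix=matrix,
    )


@dataclass
class RankedFold:
    label: str
    localized_rmsd: float | None  # None = incomparable (no admissible window)

    @property
    def comparable(self) -> bool:
        return self.localized_rmsd is not None


def rank_folds(
    query: ResidueChain,
    library: Mapping[str, ResidueChain],
    min_window: int = DEFAULT_MIN_WINDOW,
    atom_set: Sequence[str] = DEFAULT_ATOM_SET,
) -> list[RankedFold]:
    """Rank library folds by localized RMSD against the query (ascending).

    Folds sharing no admissible window with the query are reported as
    incomparable at the end of the list rather than dropped.  Ties break
    deterministically by label.
    """
    if not library:
        raise ValueError("empty fold library")
    ranked: list[RankedFold] = []
    for label in library:
        member = library[label]
        try:
            corr = correspond_by_numbering(query, member)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                matrix = window_rmsd_matrix(query, member, corr, min_window, atom_set)
            value = localized_rmsd(matrix) if matrix.entries else None
        except ValueError:
            value = None
        if value is None:
            warnings.warn(f"fold {label!r} shares no admissible window with query")
        ranked.append(RankedFold(label, value))
    ranked.sort(
        key=lambda r: (not r.comparable, r.localized_rmsd if r.comparable else 0.0, r.label)
    )
    return ranked


def render_heatmap(
    matrix: WindowRMSDMatrix,
    out_path: str | Path,
    vmin: float = 0.0,
    vmax: float | None = None,
    cmap: str = "viridis",
) -> list[Path]:
    """Triangular heat-map of the window matrix, written as PNG and SVG.

    x axis: window start residue (chain A numbering); y axis: window
    length; colour: RMSD in Å on a fixed linear scale [vmin, vmax]
    (vmax defaults to the matrix maximum).  Cells with no admissible
    window are transparent.  A sidecar JSON records the axes convention
    and colour scale.  Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not matrix.entries:
        raise ValueError("cannot render an empty matrix")
    out_path = Path(out_path)
    starts = matrix.start_numbers_a
    lengths = sorted({length for _, length in matrix.entries})
    smin, smax = int(starts.min()), int(starts.max())
    lmin, lmax = min(lengths), max(lengths)
    grid = np.full((lmax - lmin + 1, smax - smin + 1), np.nan)
    for (start, length), rmsd in matrix.entries.items():
        grid[length - lmin, int(starts[start]) - smin] = rmsd
    if vmax is None:
        vmax = float(np.nanmax(grid))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(alpha=0.0)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    im = ax.imshow(
        grid,
        origin="lower",
        aspect="auto",
        cmap=cm,
        vmin=vmin,
        vmax=vmax,
        extent=(smin - 0.5, smax + 0.5, lmin - 0.5, lmax + 0.5),
        interpolation="nearest",
    )
    ax.set_xlabel("window start residue")
    ax.set_ylabel("window length (residues)")
    ax.set_title(f"{matrix.id_a} vs {matrix.id_b} — window RMSD")
    fig.colorbar(im, ax=ax, label="RMSD (Å)")
    written: list[Path] = []
    base = out_path.with_suffix("")
    for suffix in (".png", ".svg"):
        target = base.with_suffix(suffix)
        fig.savefig(target, dpi=150, bbox_inches="tight")
        written.append(target)
    plt.close(fig)
    meta = {
        "x_axis": "window start residue (chain A numbering)",
        "y_axis": "window length (residues)",
        "color": "per-window superposed RMSD (A)",
        "vmin": vmin,
        "vmax": vmax,
        "cmap": cmap,
        "min_window": matrix.min_window,
        "atom_set": list(matrix.atom_set),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return written
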