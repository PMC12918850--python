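"""Residue correspondences between two filament folds.

Two routes produce the same data structure:

* by canonical residue number — the default, since all tauopathy
  depositions share 2N4R numbering.  Point mutants (e.g. I vs S at 305)
  are paired by number regardless of identity, and residues present in
  only one chain (3R vs 4R splicing differences) are simply unpaired.
* by global sequence alignment (Needleman–Wunsch with affine gaps) —
  the fallback when numbering schemes differ.

A correspondence is partitioned into *segments*: maximal runs where both
residue numbers advance by exactly one per step.  Segments bound the
sliding windows downstream, so no window ever spans a splicing gap or a
chain break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .structure import ResidueChain


@dataclass
class ResidueCorrespondence:
    """Monotone residue pairing between two chains.

    ``pairs`` holds (index into A.residues, index into B.residues);
    ``segments`` holds (start, stop) half-open index ranges into
    ``pairs`` partitioning it into gap-free runs.
    """

    chain_a: ResidueChain
    chain_b: ResidueChain
    pairs: list[tuple[int, int]]
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ia = [p[0] for p in self.pairs]
        ib = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(ia, ia[1:])) or any(
            b <= a for a, b in zip(ib, ib[1:])
        ):
            raise ValueError("correspondence indices must be strictly increasing")
        if not self.segments:
            self.segments = _segment(self.chain_a, self.chain_b, self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def numbers_a(self) -> np.ndarray:
        return np.array([self.chain_a.residues[i].number for i, _ in self.pairs])

    def numbers_b(self) -> np.ndarray:
        return np.array([self.chain_b.residues[j].number for _, j in self.pairs])

    def transpose(self) -> "ResidueCorrespondence":
        return ResidueCorrespondence(
            self.chain_b, self.chain_a, [(j, i) for i, j in self.pairs]
        )

    def to_tsv(self, path) -> None:
        """Two-column TSV of paired residue numbers (A then B)."""
        na, nb = self.numbers_a(), self.numbers_b()
        with open(path, "w") as fh:
            fh.write("res_a\tres_b\n")
            for a, b in zip(na, nb):
                fh.write(f"{a}\t{b}\n")


def _segment(
    chain_a: ResidueChain, chain_b: ResidueChain, pairs: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Split ``pairs`` into maximal runs where both numberings step by 1."""
    if not pairs:
        return []
    segments = []
    start = 0
    for k in range(1, len(pairs)):
        i0, j0 = pairs[k - 1]
        i1, j1 = pairs[k]
        da = chain_a.residues[i1].number - chain_a.residues[i0].number
        db = chain_b.residues[j1].number - chain_b.residues[j0].number
        if da != 1 or db != 1:
            segments.append((start, k))
            start = k
    segments.append((start, len(pairs)))
    return segments


def correspond_by_numbering(
    chain_a: ResidueChain, chain_b: ResidueChain
) -> ResidueCorrespondence:
    """Pair residues sharing a canonical residue number.

    Amino-acid identity is ignored, so point mutants stay paired; numbers
    present in only one chain (different splicing forms) are unpaired and
    split the correspondence into segments.
    """
    index_a = {r.number: i for i, r in enumerate(chain_a.residues)}
    index_b = {r.number: j for j, r in enumerate(chain_b.residues)}
    shared = sorted(set(index_a) & set(index_b))
    if not shared:
        raise ValueError(
            f"no shared residue numbers between chains "
            f"{chain_a.chain_id!r} and {chain_b.chain_id!r}"
        )
    pairs = [(index_a[n], index_b[n]) for n in shared]
    return ResidueCorrespondence(chain_a, chain_b, pairs)


def _needleman_wunsch(
    seq_a: str,
    seq_b: str,
    gap_open: float,
    gap_extend: float,
    matrix,
) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global alignment (Gotoh) with deterministic traceback.

    Gap penalties are positive magnitudes; opening a gap of length L
    costs gap_open + (L - 1) * gap_extend.  On equal scores the
    traceback prefers the diagonal (match/mismatch), then the vertical
    move (gap in B), so the alignment is reproducible across runs.
    Returns (score, pairs of 0-based indices of aligned columns).
    """
    n, m = len(seq_a), len(seq_b)
    neg = -np.inf
    # state 0 = M (diagonal), 1 = Ix (gap in B, consume A), 2 = Iy (gap in A)
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
        ptr_y[0, j] = 0 if j == 1 else 2

    def sub(i: int, j: int) -> float:
        a, b = seq_a[i - 1], seq_b[j - 1]
        try:
            return float(matrix[a, b])
        except (KeyError, IndexError):
            return 0.0

    def argbest(*cands: float) -> int:
        """Index of the max, preferring the earliest on ties (M > Ix > Iy)."""
        best = 0
        for k in range(1, len(cands)):
            if cands[k] > cands[best]:
                best = k
        return best

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(i, j)
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = argbest(*prev)
            M[i, j] = prev[k] + s
            ptr_m[i, j] = k
            open_x, ext_x = M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend
            k = argbest(open_x, ext_x)
            Ix[i, j] = (open_x, ext_x)[k]
            ptr_x[i, j] = (0, 1)[k]
            open_y, ext_y = M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend
            k = argbest(open_y, ext_y)
            Iy[i, j] = (open_y, ext_y)[k]
            ptr_y[i, j] = (0, 2)[k]

    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = argbest(*finals)
    score = finals[state]
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptr_x[i, j])
            i -= 1
        else:
            state = int(ptr_y[i, j])
            j -= 1
    pairs.reverse()
    return float(score), pairs


def alignment_score(
    seq_a: str,
    seq_b: str,
    gap_open: float = 12.0,
    gap_extend: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    matrix = substitution_matrices.load(matrix_name)
    score, _ = _needleman_wunsch(seq_a, seq_b, gap_open, gap_extend, matrix)
    return score


def correspond_by_sequence(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    gap_open: float = 12.0,
    gap_extend: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> ResidueCorrespondence:
    """Pair residues by global sequence alignment of one-letter sequences.

    Gap penalties default high relative to BLOSUM62 mismatch scores so
    splicing-sized gaps emerge rather than scattered single gaps; aligned
    non-gap columns become pairs (mismatches included, so mutants stay
    paired).
    """
    if not chain_a.residues or not chain_b.residues:
        raise ValueError("cannot align empty chains")
    matrix = substitution_matrices.load(matrix_name)
    _, pairs = _needleman_wunsch(
        chain_a.sequence, chain_b.sequence, gap_open, gap_extend, matrix
    )
    return ResidueCorrespondence(chain_a, chain_b, pairs)
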