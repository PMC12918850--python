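"""Locating deposited filament coordinate files.

Cross-deposition comparisons (e.g. the S305I Type I/II rungs against the
sporadic AGD, CBD and P301T folds) need the published coordinate files.
These are not redistributed with the package: :func:`deposition_path`
looks for ``<id>.cif`` / ``<id>.pdb`` in a local directory and, failing
that, :func:`fetch_rcsb` tries to download the mmCIF from RCSB.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

from .structure import FoldStructure, read_structure

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"

#: deposited single-protofilament tau folds used in cross-fold comparisons
KNOWN_FOLDS = {
    "S305I_type1": "10ij",
    "S305I_type2": "10ik",
    "AGD_type1": "7p66",
    "CBD": "6tjo",
}


class DepositionUnavailableError(FileNotFoundError):
    """A required deposited model is neither cached locally nor downloadable."""


def fetch_rcsb(pdb_id: str, dest_dir: str | Path, timeout: float = 15.0) -> Path:
    """Download ``<pdb_id>.cif`` from RCSB into ``dest_dir``."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    target = dest_dir / f"{pdb_id.lower()}.cif"
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            target.write_bytes(resp.read())
    except (urllib.error.URLError, OSError) as exc:
        raise DepositionUnavailableError(
            f"cannot download {pdb_id.upper()} from {url}: {exc}"
        ) from exc
    return target


def deposition_path(
    pdb_id: str, search_dir: str | Path, download: bool = True
) -> Path:
    """Find a deposited model locally, downloading it if allowed and needed."""
    search_dir = Path(search_dir)
    for suffix in (".cif", ".pdb", ".ent"):
        candidate = search_dir / f"{pdb_id.lower()}{suffix}"
        if candidate.exists():
            return candidate
        candidate = search_dir / f"{pdb_id.upper()}{suffix}"
        if candidate.exists():
            return candidate
    if download:
        return fetch_rcsb(pdb_id, search_dir)
    raise DepositionUnavailableError(
        f"deposited model {pdb_id} not found under {search_dir}"
    )


def load_deposited_fold(
    pdb_id: str, search_dir: str | Path, download: bool = True
) -> FoldStructure:
    """Read a deposited filament model, fetching it first if necessary."""
    return read_structure(deposition_path(pdb_id, search_dir, download=download))
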