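"""Cα trace container and structure-file I/O.

A :class:`CaTrace` is the object every other module operates on: the
ordered Cα coordinates of a single protein chain (or domain selection),
with a 1-based sequential index used for all residue-separation tests.
Author residue numbering is retained for provenance only — ASTRAL-style
domains frequently have gapped or re-numbered sequences, so algorithmic
decisions never consult it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import InputError

#: smallest trace the scan machinery accepts: shifts run to N-3 and the
#: last initial alignment needs at least 3 pairs, plus headroom for seeds
MIN_RESIDUES = 8


@dataclass(frozen=True)
class ResidueId:
    """Provenance identity of one residue (never used algorithmically)."""

    chain: str
    number: int
    icode: str = ""
    name: str = "GLY"


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one domain.

    Parameters
    ----------
    coords
        (N, 3) float array of Cα positions in Å, in file/sequence order.
    residue_ids
        Per-residue provenance (chain, author number, insertion code).
        May be empty, in which case synthetic placeholder ids are used.
    label
        Free-text domain name carried through reports.
    """

    coords: np.ndarray
    residue_ids: tuple[ResidueId, ...] = ()
    label: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coords must be (N, 3); got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise InputError("coords contain non-finite values")
        if len(coords) < MIN_RESIDUES:
            raise InputError(
                f"too few residues: {len(coords)} < {MIN_RESIDUES} "
                "(an alignment scan needs shifts up to N-3 with 3-pair seeds)"
            )
        object.__setattr__(self, "coords", coords)
        ids = tuple(self.residue_ids)
        if ids and len(ids) != len(coords):
            raise InputError("residue_ids length does not match coords")
        if not ids:
            ids = tuple(ResidueId("A", i + 1) for i in range(len(coords)))
        object.__setattr__(self, "residue_ids", ids)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    @property
    def seq_index(self) -> np.ndarray:
        """1-based contiguous index; the index used in all |i-j| tests."""
        return np.arange(1, len(self.coords) + 1)


@dataclass(frozen=True)
class Selector:
    """Chain / author-residue-range selection applied when reading a file."""

    chain: str | None = None
    start: int | None = None  # author numbering, inclusive
    end: int | None = None  # author numbering, inclusive

    def matches(self, chain: str, number: int) -> bool:
        if self.chain is not None and chain != self.chain:
            return False
        if self.start is not None and number < self.start:
            return False
        if self.end is not None and number > self.end:
            return False
        return True


def _best_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA atom of a residue (ties: first encountered)."""
    best = None
    for atom in residue:
        # exclude calcium ions, whose atom name is also "CA"
        if atom.name != "CA" or atom.element.name == "Ca":
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_ca_trace(
    path: str | Path, selector: Selector | None = None, label: str | None = None
) -> tuple[CaTrace, int]:
    """Read a PDB or mmCIF file and extract one Cα trace.

    Residues without a Cα atom are skipped and counted; alternate
    locations resolve to the highest-occupancy conformer. Waters and
    non-polymer ligands are ignored; modified residues (MSE etc.) that
    carry a Cα are kept.

    Returns
    -------
    (trace, n_skipped)
        The trace and the number of selected residues lacking a Cα.
    """
    path = Path(path)
    selector = selector or Selector()
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise InputError(f"cannot read structure file {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise InputError(f"{path}: no models in file")
    model = structure[0]

    coords: list[list[float]] = []
    ids: list[ResidueId] = []
    n_selected = 0
    n_skipped = 0
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            info = gemmi.find_tabulated_residue(residue.name)
            is_aa = info is not None and info.is_amino_acid()
            ca = _best_ca(residue)
            if not is_aa and ca is None:
                continue  # ligands, ions etc.
            if not selector.matches(chain.name, residue.seqid.num):
                continue
            n_selected += 1
            if ca is None:
                n_skipped += 1
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            ids.append(
                ResidueId(
                    chain.name,
                    residue.seqid.num,
                    residue.seqid.icode.strip(),
                    residue.name,
                )
            )
    if n_selected == 0:
        raise InputError(f"{path}: selection matched no residues")
    if len(coords) < MIN_RESIDUES:
        raise InputError(
            f"{path}: too few residues with a Ca atom "
            f"({len(coords)} < {MIN_RESIDUES})"
        )
    trace = CaTrace(np.array(coords), tuple(ids), label or path.stem)
    return trace, n_skipped


def write_ca_pdb(trace: CaTrace, path: str | Path) -> None:
    """Write the trace as a minimal Cα-only PDB file."""
    path = Path(path)
    lines = []
    for serial, (xyz, rid) in enumerate(zip(trace.coords, trace.residue_ids), 1):
        lines.append(
            f"ATOM  {serial:5d}  CA  {rid.name:<3s} {rid.chain[:1]:1s}"
            f"{rid.number:4d}{(rid.icode or ' '):1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
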