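"""Structure-ensemble container, atom selections, and coordinate I/O.

A :class:`StructureEnsemble` is the object all conformational-state analysis
consumes: a stack of frames over a fixed atom list, with per-atom residue and
atom labels.  Coordinates are stored in nm; PDB files (which are in Angstrom)
are converted on read/write.

Selections are expressed as residue ranges plus an atom-name filter
(:class:`SelectionSpec`).  The module ships the selections used by the
N-SH2-style analysis: the rigid core used for least-squares fitting, the
backbone analysis set, and the pY-loop and +5-site subsets (SHP2 residue
numbering).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import A_PER_NM

__all__ = [
    "StructureEnsemble",
    "SelectionSpec",
    "CORE_FIT_RANGES",
    "ANALYSIS_RANGES",
    "PY_LOOP_RANGES",
    "PLUS5_RANGES",
    "core_fit_selection",
    "analysis_selection",
    "py_loop_selection",
    "plus5_selection",
    "read_pdb",
    "write_pdb",
    "read_frame_table",
    "write_frame_table",
]

#: Residue ranges (inclusive, SHP2 numbering) of the relatively rigid core of
#: the domain, used for least-squares fitting before PCA.
CORE_FIT_RANGES = ((7, 33), (40, 47), (50, 58), (61, 65), (71, 81), (88, 90), (95, 101))

#: Residue range of the PCA analysis set (backbone, excluding flexible termini).
ANALYSIS_RANGES = ((6, 101),)

#: pY-loop subset used for the loop subvector.
PY_LOOP_RANGES = ((34, 41),)

#: +5-site subset (end of the βD strand through the BG loop).
PLUS5_RANGES = ((57, 97),)

_BACKBONE_SENTINEL = "backbone"


@dataclass(frozen=True)
class SelectionSpec:
    """Named residue ranges with an atom-name filter.

    ``atom_names`` may be an explicit tuple of names, ``"backbone"`` (N, CA, C
    plus O when the ensemble contains O atoms), or ``None`` for all atoms.
    """

    ranges: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] | str | None = _BACKBONE_SENTINEL
    name: str = ""

    def _atom_name_set(self, ensemble: "StructureEnsemble") -> set[str] | None:
        if self.atom_names is None:
            return None
        if self.atom_names == _BACKBONE_SENTINEL:
            names = {"N", "CA", "C"}
            if "O" in set(ensemble.atom_names):
                names.add("O")
            return names
        return set(self.atom_names)

    def resolve(self, ensemble: "StructureEnsemble") -> np.ndarray:
        """Return sorted atom indices selected on *ensemble*.

        Raises ``ValueError`` when the selection resolves to no atoms.
        """
        names = self._atom_name_set(ensemble)
        resnum = ensemble.residue_numbers
        mask = np.zeros(ensemble.n_atoms, dtype=bool)
        for lo, hi in self.ranges:
            mask |= (resnum >= lo) & (resnum <= hi)
        if names is not None:
            mask &= np.isin(ensemble.atom_names, sorted(names))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(
                f"selection {self.name or self.ranges!r} resolves to no atoms"
            )
        return idx


def core_fit_selection() -> SelectionSpec:
    return SelectionSpec(CORE_FIT_RANGES, name="core")


def analysis_selection() -> SelectionSpec:
    return SelectionSpec(ANALYSIS_RANGES, name="analysis")


def py_loop_selection() -> SelectionSpec:
    return SelectionSpec(PY_LOOP_RANGES, name="py_loop")


def plus5_selection() -> SelectionSpec:
    return SelectionSpec(PLUS5_RANGES, name="plus5")


@dataclass
class StructureEnsemble:
    """Frames x atoms x 3 coordinates (nm) with per-atom labels."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3), nm
    residue_numbers: np.ndarray  # (n_atoms,) int
    residue_names: np.ndarray  # (n_atoms,) str
    atom_names: np.ndarray  # (n_atoms,) str
    provenance: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        if self.coordinates.ndim != 3 or self.coordinates.shape[-1] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        n = self.coordinates.shape[1]
        for arr, what in (
            (self.residue_numbers, "residue_numbers"),
            (self.residue_names, "residue_names"),
            (self.atom_names, "atom_names"),
        ):
            if len(arr) != n:
                raise ValueError(f"{what} length {len(arr)} != n_atoms {n}")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> "StructureEnsemble":
        """Single-frame ensemble sharing the atom labels."""
        return replace(self, coordinates=self.coordinates[i : i + 1].copy())

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        """Index of a uniquely labelled atom; raises naming the atom if absent."""
        hits = np.flatnonzero(
            (self.residue_numbers == residue_number) & (self.atom_names == atom_name)
        )
        if hits.size == 0:
            raise KeyError(f"atom {atom_name} of residue {residue_number} not present")
        if hits.size > 1:
            raise KeyError(
                f"atom {atom_name} of residue {residue_number} is not unique"
            )
        return int(hits[0])

    def with_coordinates(self, coords: np.ndarray, provenance: str | None = None):
        return replace(
            self,
            coordinates=np.asarray(coords, dtype=float),
            provenance=self.provenance if provenance is None else provenance,
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite backend)
# ---------------------------------------------------------------------------

def read_pdb(path, chain: str | None = None) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a StructureEnsemble.

    Residue numbering is taken verbatim from the file.  Altloc handling keeps
    the first location ('A' or blank); insertion codes are rejected with a
    clear error because the SHP2 numbering the analysis relies on is
    ambiguous in their presence.
    """
    import biotite.structure as struc
    from biotite.structure.io import pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, altloc="first")
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    if chain is not None:
        mask = stack.chain_id == chain
        if not mask.any():
            raise ValueError(f"chain {chain!r} not found in {path}")
        stack = stack[..., mask]
    if "ins_code" in stack.get_annotation_categories():
        ins = np.asarray(stack.ins_code)
        bad = ins != ""
        if bad.any():
            res = stack.res_id[bad][0]
            raise ValueError(
                f"insertion codes present (first at residue {res}); "
                "renumber the structure before analysis"
            )
    return StructureEnsemble(
        coordinates=np.asarray(stack.coord, dtype=float) / A_PER_NM,
        residue_numbers=np.asarray(stack.res_id),
        residue_names=np.asarray(stack.res_name, dtype=object),
        atom_names=np.asarray(stack.atom_name, dtype=object),
        provenance=f"pdb:{path}" + (f":chain={chain}" if chain else ""),
    )


def write_pdb(ensemble: StructureEnsemble, path, chain: str = "A") -> None:
    """Write the ensemble as a multi-MODEL PDB file (coordinates in Angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io import pdb as pdbio

    n = ensemble.n_atoms
    arrays = []
    for f in range(ensemble.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = ensemble.coordinates[f] * A_PER_NM
        arr.chain_id = np.full(n, chain)
        arr.res_id = ensemble.residue_numbers.astype(int)
        arr.res_name = ensemble.residue_names.astype(str)
        arr.atom_name = ensemble.atom_names.astype(str)
        arr.element = np.array(
            [str(nm)[0] for nm in ensemble.atom_names], dtype="U2"
        )
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(struc.stack(arrays))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text frame table
# ---------------------------------------------------------------------------

_FRAME_TABLE_COLUMNS = ["frame", "residue_number", "residue_name", "atom_name",
                        "x_nm", "y_nm", "z_nm"]


def write_frame_table(ensemble: StructureEnsemble, path) -> None:
    """Write the package's plain-text multi-frame coordinate table (nm)."""
    rows = []
    for f in range(ensemble.n_frames):
        for a in range(ensemble.n_atoms):
            x, y, z = ensemble.coordinates[f, a]
            rows.append(
                (f, ensemble.residue_numbers[a], ensemble.residue_names[a],
                 ensemble.atom_names[a], x, y, z)
            )
    df = pd.DataFrame(rows, columns=_FRAME_TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# nsh2kit frame table; coordinates in nm\n")
        fh.write("# columns: " + " ".join(_FRAME_TABLE_COLUMNS) + "\n")
        df.to_csv(fh, sep=" ", header=False, index=False,
                  float_format="%.6f")


def read_frame_table(path) -> StructureEnsemble:
    with open(path) as fh:
        text = fh.read()
    df = pd.read_csv(
        _io.StringIO(text), sep=r"\s+", comment="#", header=None,
        names=_FRAME_TABLE_COLUMNS,
    )
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    n_atoms = len(first)
    coords = np.empty((len(frames), n_atoms, 3))
    for i, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != n_atoms:
            raise ValueError(f"frame {f} has {len(sub)} atoms, expected {n_atoms}")
        coords[i] = sub[["x_nm", "y_nm", "z_nm"]].to_numpy()
    return StructureEnsemble(
        coordinates=coords,
        residue_numbers=first["residue_number"].to_numpy(),
        residue_names=first["residue_name"].to_numpy(dtype=object),
        atom_names=first["atom_name"].to_numpy(dtype=object),
        provenance=f"frame_table:{path}",
    )
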