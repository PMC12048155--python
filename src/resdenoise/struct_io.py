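"""Backbone structure I/O and idealized peptide geometry.

Reads PDB-format text (ATOM records) into an ordered per-residue
representation carrying the five backbone-level atoms used downstream
(N, CA, C, O and a real or virtual CB), and writes it back out.  Parsing is
delegated to :mod:`biotite`; altloc conflicts are resolved by highest
occupancy, only the first MODEL of multi-model files is used, and HETATM
ligands/waters, ANISOU and header records are ignored.  Non-standard
residues are mapped to their canonical parent when known (e.g. MSE to M),
otherwise to ``'X'``; such residues stay in the chain so the residue-graph
topology is unaffected.

Coordinates are in Angstrom and residue positions are 1-based throughout
the package, matching the "A24G" deep-mutational-scanning convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ChainNotFoundError, GeometryError, ParseError

#: Sentinel accepted by :func:`parse_structure` to take every chain.
ALL_CHAINS = "*"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common non-standard residues -> canonical parent
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "CSO": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y", "MLY": "K", "KCX": "K",
}

_ONE_TO_THREE = {v: k for k, v in reversed(list(_THREE_TO_ONE.items()))}
_ONE_TO_THREE["X"] = "UNK"

# Ideal peptide internal coordinates (lengths in A, angles in degrees).
IDEAL_N_CA = 1.458
IDEAL_CA_C = 1.525
IDEAL_C_N = 1.329
IDEAL_C_O = 1.231
IDEAL_ANGLE_N_CA_C = 111.2
IDEAL_ANGLE_CA_C_N = 116.2
IDEAL_ANGLE_C_N_CA = 121.7
IDEAL_ANGLE_CA_C_O = 120.5
#: Default N-CA-C-O dihedral used when O must be reconstructed without
#: knowledge of the next residue (an alpha-helical value).
DEFAULT_O_DIHEDRAL = 135.0


@dataclass
class ResidueRecord:
    """One residue with its backbone-level atoms.

    ``seq_index`` is the 1-based position within the extracted chain
    sequence (insertion-coded residues are numbered in file order).
    """

    chain_id: str
    seq_index: int
    aa: str
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    CB: np.ndarray
    cb_is_virtual: bool = False
    o_is_reconstructed: bool = False

    def backbone(self) -> np.ndarray:
        """Stacked (5, 3) array of N, CA, C, O, CB coordinates."""
        return np.stack([self.N, self.CA, self.C, self.O, self.CB])

    def validate(self) -> None:
        bb = self.backbone()
        if not np.all(np.isfinite(bb)):
            raise GeometryError(f"residue {self.seq_index}: non-finite coordinates")
        for a, b, lo, hi in (
            ("N", "CA", 0.5, 3.0),
            ("CA", "C", 0.5, 3.0),
            ("N", "C", 0.5, 3.0),
            ("C", "O", 0.5, 2.0),
            ("CA", "CB", 1.0, 2.2),
        ):
            d = float(np.linalg.norm(getattr(self, a) - getattr(self, b)))
            if not lo <= d <= hi:
                raise GeometryError(
                    f"residue {self.seq_index}: {a}-{b} distance {d:.2f} A "
                    f"outside [{lo}, {hi}]"
                )


@dataclass
class ProteinStructure:
    """Ordered residues of a protein with its one-letter sequence."""

    id: str
    residues: list = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.stack([r.CA for r in self.residues])

    def validate(self) -> None:
        for r in self.residues:
            r.validate()
        by_chain: dict = {}
        for r in self.residues:
            prev = by_chain.get(r.chain_id)
            if prev is not None and r.seq_index <= prev:
                raise ParseError(
                    f"residue order not strictly increasing in chain {r.chain_id}"
                )
            by_chain[r.chain_id] = r.seq_index


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain a-b-c.

    D is bonded to ``c`` at ``bond_length``, with bond angle b-c-D and
    dihedral a-b-c-D (natural extension of reference frame, the standard
    internal-to-Cartesian construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.deg2rad(bond_angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nbc < 1e-8 or nn < 1e-8:
        raise GeometryError("collinear or coincident reference atoms")
    bc /= nbc
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(chi),
            bond_length * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cbeta(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta position from backbone N, CA, C.

    Uses the standard linear-combination construction; the result sits
    ~1.53 A from CA and transforms equivariantly under rigid motions.
    Raises :class:`GeometryError` for collinear input.
    """
    N, CA, C = (np.asarray(p, dtype=float) for p in (N, CA, C))
    b = CA - N
    c = C - CA
    a = np.cross(b, c)
    if np.linalg.norm(a) < 1e-8:
        raise GeometryError("backbone atoms are collinear; cannot place C-beta")
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + CA


def reconstruct_oxygen(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Carbonyl O from ideal geometry when the atom is missing."""
    return place_atom(N, CA, C, IDEAL_C_O, IDEAL_ANGLE_CA_C_O, DEFAULT_O_DIHEDRAL)


def _one_letter(res_name: str) -> str:
    return _THREE_TO_ONE.get(res_name.upper(), "X")


def parse_structure(pdb_text: str, chain: str = ALL_CHAINS, id: str = "protein") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Parameters
    ----------
    pdb_text:
        PDB file content with at least one ATOM record.
    chain:
        Chain identifier to extract, or :data:`ALL_CHAINS` for every chain
        (in file order).
    id:
        Identifier attached to the returned structure.

    Raises
    ------
    ParseError
        If the text contains no parseable ATOM records.
    ChainNotFoundError
        If the requested chain is absent.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise ParseError("no ATOM records found")
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various error types
        raise ParseError(f"cannot parse PDB text: {exc}") from exc
    if atoms.array_length() == 0:
        raise ParseError("no ATOM records found")

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ParseError("no amino-acid ATOM records found")
    if chain != ALL_CHAINS:
        atoms = atoms[atoms.chain_id == chain]
        if atoms.array_length() == 0:
            raise ChainNotFoundError(f"chain {chain!r} not found")

    residues = []
    counters: dict = {}
    for res_atoms in struc.residue_iter(atoms):
        names = list(res_atoms.atom_name)
        coords = {n: res_atoms.coord[i] for i, n in enumerate(names)}
        if not {"N", "CA", "C"} <= set(names):
            continue  # incomplete backbone: skip the residue
        cid = str(res_atoms.chain_id[0])
        counters[cid] = counters.get(cid, 0) + 1
        aa = _one_letter(str(res_atoms.res_name[0]))
        N, CA, C = coords["N"], coords["CA"], coords["C"]
        o_missing = "O" not in coords
        O = reconstruct_oxygen(N, CA, C) if o_missing else coords["O"]
        cb_missing = "CB" not in coords
        CB = virtual_cbeta(N, CA, C) if cb_missing else coords["CB"]
        residues.append(
            ResidueRecord(
                chain_id=cid,
                seq_index=counters[cid],
                aa=aa,
                N=np.asarray(N, dtype=float),
                CA=np.asarray(CA, dtype=float),
                C=np.asarray(C, dtype=float),
                O=np.asarray(O, dtype=float),
                CB=np.asarray(CB, dtype=float),
                cb_is_virtual=cb_missing,
                o_is_reconstructed=o_missing,
            )
        )
    if not residues:
        raise ParseError("no residues with complete N/CA/C backbone")
    return ProteinStructure(id=id, residues=residues)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure back to PDB-format text.

    Only backbone-level atoms are written; virtual CB atoms are omitted so
    that a parse/write/parse round trip reproduces the same flags.
    """
    records = []
    for r in structure.residues:
        atom_set = [("N", r.N), ("CA", r.CA), ("C", r.C), ("O", r.O)]
        if not r.cb_is_virtual:
            atom_set.append(("CB", r.CB))
        for name, coord in atom_set:
            records.append((r, name, coord))

    arr = struc.AtomArray(len(records))
    for i, (r, name, coord) in enumerate(records):
        arr.coord[i] = coord
        arr.chain_id[i] = r.chain_id
        arr.res_id[i] = r.seq_index
        arr.res_name[i] = _ONE_TO_THREE.get(r.aa, "UNK")
        arr.atom_name[i] = name
        arr.element[i] = name[0]
        arr.hetero[i] = False
    pdb = PDBFile()
    pdb.set_structure(arr)
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


def write_fasta(structures, path_or_buf) -> None:
    """Write extracted sequences as FASTA."""
    from biotite.sequence.io.fasta import FastaFile

    fasta = FastaFile()
    for s in structures:
        fasta[s.id] = s.sequence
    if hasattr(path_or_buf, "write"):
        fasta.write(path_or_buf)
    else:
        with open(path_or_buf, "w") as fh:
            fasta.write(fh)


def structure_from_arrays(
    id: str,
    sequence: str,
    N: np.ndarray,
    CA: np.ndarray,
    C: np.ndarray,
    O: np.ndarray,
    chain_id: str = "A",
) -> ProteinStructure:
    """Assemble a structure from per-residue backbone coordinate arrays.

    CB is always virtual (used by the fixture generator)."""
    residues = []
    for i, aa in enumerate(sequence):
        cb = virtual_cbeta(N[i], CA[i], C[i])
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                seq_index=i + 1,
                aa=aa,
                N=np.asarray(N[i], float),
                CA=np.asarray(CA[i], float),
                C=np.asarray(C[i], float),
                O=np.asarray(O[i], float),
                CB=cb,
                cb_is_virtual=True,
            )
        )
    return ProteinStructure(id=id, residues=residues)
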