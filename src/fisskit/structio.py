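"""Coordinate model I/O, atom selection and rigid superposition.

Structures are read with gemmi (fixed-column PDB and mmCIF) into a plain
:class:`StructureModel` that keeps author residue numbering, drops
hydrogens and waters, and resolves alternate locations to the highest
occupancy conformer (ties broken lexicographically by altloc id).
Superposition is a hand-written Kabsch solver (SVD with reflection guard),
since the least-squares rigid fit between equivalent atom sets is one of
the quantities this package exists to compute.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import numpy as np
import gemmi

from .errors import (
    AtomMissingError,
    DegenerateGeometryError,
    FormatError,
    ParseError,
    SelectionError,
)

__all__ = [
    "Atom",
    "StructureModel",
    "AtomSelection",
    "Superposition",
    "read_structure",
    "write_pdb",
    "select_atoms",
    "superpose",
    "apply_superposition",
    "chain_sequence",
    "align_calpha",
]

#: three-letter -> one-letter amino acid codes (standard residues only)
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclasses.dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    pos: tuple  # (x, y, z) in A


@dataclasses.dataclass
class StructureModel:
    """Atoms of one model of a coordinate file.

    ``models`` maps model id -> atom list for multi-model (NMR) files;
    ``atoms`` is the atom list of ``model_id`` (default: first model).
    """

    atoms: list
    model_id: int = 1
    source_id: str = ""
    models: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.models:
            self.models = {self.model_id: self.atoms}
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resnum, a.name)
            if key in seen:
                raise ParseError(
                    f"duplicate atom {key} in model {self.model_id} of {self.source_id}"
                )
            seen.add(key)
            if not np.all(np.isfinite(a.pos)):
                raise ParseError(f"non-finite position for {key}")

    @property
    def model_ids(self):
        return sorted(self.models)

    def model(self, model_id: int) -> "StructureModel":
        """Return a view of another model of the same file."""
        if model_id not in self.models:
            raise SelectionError(
                f"model {model_id} not in {self.source_id}; have {self.model_ids}"
            )
        return StructureModel(
            atoms=self.models[model_id],
            model_id=model_id,
            source_id=self.source_id,
            models=self.models,
        )

    def chains(self):
        out = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def positions(self, atom_name: str = "CA", chain: str | None = None) -> np.ndarray:
        sel = [
            a.pos
            for a in self.atoms
            if a.name == atom_name and (chain is None or a.chain == chain)
        ]
        return np.asarray(sel, dtype=float)


@dataclasses.dataclass(frozen=True)
class AtomSelection:
    """Chain + inclusive author-numbered residue range + atom-name filter."""

    chain: str
    first: int
    last: int
    atom: str = "CA"

    def __post_init__(self):
        if self.last < self.first:
            raise SelectionError(
                f"empty residue range {self.first}-{self.last} on chain {self.chain}"
            )


@dataclasses.dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float  # A, over the stated correspondence
    n_atoms: int

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise DegenerateGeometryError("rotation is not orthonormal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


def _pick_altloc(group: list) -> gemmi.Atom:
    # highest occupancy wins; ties broken by lexicographic altloc id
    return sorted(group, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    All models are retained (``model()`` selects); hydrogens and waters are
    dropped; altlocs resolved to the highest-occupancy conformer. Files with
    insertion codes in the retained records are rejected: author numbering
    is used as-is throughout the package and would become ambiguous.
    """
    path = os.fspath(path)
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(path, format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    models: dict[int, list] = {}
    for imodel, model in enumerate(st, start=1):
        mid = getattr(model, "num", None)
        if mid is None:
            try:
                mid = int(model.name)
            except (ValueError, TypeError, AttributeError):
                mid = imodel
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                if res.is_water():
                    continue
                if res.seqid.icode not in ("", " ", "\x00"):
                    raise ParseError(
                        f"insertion code {res.seqid.icode!r} at "
                        f"{chain.name}/{res.seqid.num} in {path}; not supported"
                    )
                by_name: dict[str, list] = {}
                for at in res:
                    if at.is_hydrogen():
                        continue
                    by_name.setdefault(at.name, []).append(at)
                for name, group in by_name.items():
                    at = _pick_altloc(group)
                    atoms.append(
                        Atom(
                            chain=chain.name,
                            resnum=res.seqid.num,
                            resname=res.name,
                            name=name,
                            pos=(at.pos.x, at.pos.y, at.pos.z),
                        )
                    )
        if atoms:
            models[mid] = atoms
    if not models:
        raise ParseError(f"no atoms found in {path}")
    first = sorted(models)[0]
    return StructureModel(
        atoms=models[first],
        model_id=first,
        source_id=os.path.basename(path),
        models=models,
    )


_PDB_LINE = (
    "ATOM  {serial:5d} {name:<4s}{alt:1s}{resname:<3s} {chain:1s}"
    "{resnum:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_pdb(model: StructureModel, path: str | os.PathLike, all_models: bool = False):
    """Write fixed-column PDB (fixture writer; 1e-3 A coordinate precision)."""
    model_ids = model.model_ids if all_models else [model.model_id]
    with open(path, "w") as fh:
        for mid in model_ids:
            if len(model_ids) > 1:
                fh.write(f"MODEL     {mid:4d}\n")
            serial = 0
            for a in model.models[mid]:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    _PDB_LINE.format(
                        serial=serial,
                        name=name,
                        alt=" ",
                        resname=a.resname,
                        chain=a.chain[:1] or "A",
                        resnum=a.resnum,
                        icode=" ",
                        x=a.pos[0],
                        y=a.pos[1],
                        z=a.pos[2],
                        occ=1.0,
                        b=0.0,
                        element=a.name[:1],
                    )
                )
            if len(model_ids) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def select_atoms(model: StructureModel, sel: AtomSelection) -> np.ndarray:
    """Positions of ``sel.atom`` for the residue range, ordered by residue number.

    Raises SelectionError listing the residues that failed to resolve
    (e.g. glycines in a C-beta selection).
    """
    wanted = range(sel.first, sel.last + 1)
    by_res: dict[int, Atom] = {}
    present: dict[int, str] = {}
    for a in model.atoms:
        if a.chain != sel.chain or a.resnum not in wanted:
            continue
        present[a.resnum] = a.resname
        if a.name == sel.atom:
            by_res[a.resnum] = a
    missing = [r for r in wanted if r in present and r not in by_res]
    absent = [r for r in wanted if r not in present]
    if missing or not by_res:
        detail = []
        if missing:
            detail.append(
                "no atom %r in residues %s"
                % (sel.atom, ", ".join(f"{present[r]}{r}" for r in missing))
            )
        if absent:
            detail.append(f"residues absent from chain {sel.chain}: {absent}")
        if not by_res:
            detail.append("selection resolved to zero atoms")
        raise SelectionError(
            f"selection {sel.chain}/{sel.first}-{sel.last}/{sel.atom}: "
            + "; ".join(detail)
        )
    return np.asarray([by_res[r].pos for r in sorted(by_res)], dtype=float)


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal rotation R, translation t minimising |R P + t - Q|^2 (row vectors)."""
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    return R, t


def superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    correspondence: Sequence[tuple] | None = None,
) -> Superposition:
    """Least-squares rigid superposition (Kabsch) of mobile onto target.

    ``correspondence`` is a sequence of (mobile index, target index) pairs;
    by default atom i maps to atom i. At least three non-collinear pairs
    are required.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if correspondence is None:
        if len(mobile) != len(target):
            raise DegenerateGeometryError(
                "point counts differ and no correspondence was given"
            )
        correspondence = [(i, i) for i in range(len(mobile))]
    idx_m = [i for i, _ in correspondence]
    idx_t = [j for _, j in correspondence]
    P = mobile[idx_m]
    Q = target[idx_t]
    if len(P) < 3:
        raise DegenerateGeometryError(f"need >=3 correspondence pairs, got {len(P)}")
    # collinearity: rank of the centred point cloud
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-8) < 2:
        raise DegenerateGeometryError("correspondence points are collinear")
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


def apply_superposition(sup: Superposition, points: np.ndarray) -> np.ndarray:
    return np.asarray(points, float) @ sup.rotation.T + sup.translation


def chain_sequence(model: StructureModel, chain: str, first=None, last=None):
    """(residue numbers, one-letter sequence) of CA-bearing residues of a chain."""
    rows = []
    for a in model.atoms:
        if a.chain == chain and a.name == "CA":
            if first is not None and a.resnum < first:
                continue
            if last is not None and a.resnum > last:
                continue
            rows.append((a.resnum, AA3TO1.get(a.resname, "X")))
    rows.sort()
    nums = [r for r, _ in rows]
    seq = "".join(c for _, c in rows)
    return nums, seq


def align_calpha(
    model_a: StructureModel,
    chain_a: str,
    model_b: StructureModel,
    chain_b: str,
    range_a: tuple | None = None,
    range_b: tuple | None = None,
):
    """CA correspondence between two (possibly non-identical) sequences.

    Global pairwise alignment (match +1, mismatch 0, gap -5); CA pairs are
    taken at aligned non-gap columns. Returns (positions_a, positions_b)
    with one row per aligned pair.
    """
    from Bio import Align

    fa, la = range_a if range_a else (None, None)
    fb, lb = range_b if range_b else (None, None)
    nums_a, seq_a = chain_sequence(model_a, chain_a, fa, la)
    nums_b, seq_b = chain_sequence(model_b, chain_b, fb, lb)
    if not seq_a or not seq_b:
        raise SelectionError("empty sequence for alignment")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -5
    aln = aligner.align(seq_a, seq_b)[0]
    pos_a, pos_b = [], []
    ca_a = {
        a.resnum: a.pos for a in model_a.atoms if a.chain == chain_a and a.name == "CA"
    }
    ca_b = {
        a.resnum: a.pos for a in model_b.atoms if a.chain == chain_b and a.name == "CA"
    }
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            pos_a.append(ca_a[nums_a[i]])
            pos_b.append(ca_b[nums_b[j]])
    return np.asarray(pos_a, float), np.asarray(pos_b, float)
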