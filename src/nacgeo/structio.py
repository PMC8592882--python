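"""Structures, multi-model-PDB trajectories, and atom selections.

The trajectory format is multi-model PDB: each ``MODEL``/``ENDMDL`` block is
one frame, and atom identities must be constant across frames.  Parsing and
writing are backed by :mod:`biotite`; this module adds the trajectory
container, the deterministic altloc policy (highest occupancy, first on
tie), and a small selection mini-language::

    chain A and resid 186-216 and name CA
    protein and not hydrogen
    resname ALA GLY or hetero

Keywords: ``chain``, ``resid`` (single ids, comma lists, ``lo-hi`` ranges),
``resname``, ``name``, ``element``, ``serial``, and the bare predicates
``protein``, ``hetero``, ``hydrogen``, ``backbone``, ``all``; combined with
``and`` / ``or`` / ``not`` and parentheses.  ``protein`` means standard
amino-acid residues from ATOM records, so waters and ligands (HETATM) are
excluded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "SelectionError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "select",
    "RAT_TO_HUMAN_RESID_OFFSET",
]

#: Residue-number offset between rat PRMT1 (1OR8 numbering, dimer arm
#: 186-216, W197/Y202/M206) and human PRMT1 variant 2 (6NT2 numbering,
#: arm 204-234, W215/Y220/M224).  human resid = rat resid + 18.
RAT_TO_HUMAN_RESID_OFFSET = 18

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE HID HIE HIP ASH GLH LYN CYX CYM".split()
)
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBFormatError(ValueError):
    """Raised for malformed or inconsistent PDB input/output."""


class SelectionError(ValueError):
    """Raised for a malformed selection expression."""


@dataclass(frozen=True)
class Atom:
    """One atom record (PDB column conventions; resid as printed, 1-based)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    icode: str
    chain: str
    altloc: str
    occupancy: float
    bfactor: float
    hetero: bool


class Structure:
    """An ordered set of atoms with one coordinate per atom (Å).

    Stored column-wise (one numpy array per field) for vectorised analysis;
    :attr:`atoms` materialises row-wise :class:`Atom` records on demand.
    """

    _FIELDS = (
        "serial", "name", "element", "resname", "resid",
        "icode", "chain", "altloc", "occupancy", "bfactor", "hetero",
    )

    def __init__(
        self,
        *,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        resname: np.ndarray,
        resid: np.ndarray,
        icode: np.ndarray,
        chain: np.ndarray,
        altloc: np.ndarray,
        occupancy: np.ndarray,
        bfactor: np.ndarray,
        hetero: np.ndarray,
        coords: np.ndarray,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        n = coords.shape[0]
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.resname = np.asarray(resname, dtype="U5")
        self.resid = np.asarray(resid, dtype=int)
        self.icode = np.asarray(icode, dtype="U1")
        self.chain = np.asarray(chain, dtype="U4")
        self.altloc = np.asarray(altloc, dtype="U1")
        self.occupancy = np.asarray(occupancy, dtype=float)
        self.bfactor = np.asarray(bfactor, dtype=float)
        self.hetero = np.asarray(hetero, dtype=bool)
        for f in self._FIELDS:
            if len(getattr(self, f)) != n:
                raise ValueError(f"field {f!r} has length {len(getattr(self, f))}, expected {n}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.coords = coords

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, coords, *, name, element, resname, resid, chain,
                    hetero=None, serial=None, icode=None, altloc=None,
                    occupancy=None, bfactor=None) -> "Structure":
        """Build a structure supplying only the fields that matter."""
        n = len(np.asarray(coords))
        return cls(
            coords=coords,
            serial=np.arange(1, n + 1) if serial is None else serial,
            name=name,
            element=element,
            resname=resname,
            resid=resid,
            icode=np.full(n, "", dtype="U1") if icode is None else icode,
            chain=chain,
            altloc=np.full(n, "", dtype="U1") if altloc is None else altloc,
            occupancy=np.ones(n) if occupancy is None else occupancy,
            bfactor=np.zeros(n) if bfactor is None else bfactor,
            hetero=np.zeros(n, dtype=bool) if hetero is None else hetero,
        )

    # -- basic protocol -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                serial=int(self.serial[i]), name=str(self.name[i]),
                element=str(self.element[i]), resname=str(self.resname[i]),
                resid=int(self.resid[i]), icode=str(self.icode[i]),
                chain=str(self.chain[i]), altloc=str(self.altloc[i]),
                occupancy=float(self.occupancy[i]), bfactor=float(self.bfactor[i]),
                hetero=bool(self.hetero[i]),
            )
            for i in range(self.n_atoms)
        ]

    def subset(self, indices: Sequence[int]) -> "Structure":
        """New structure containing the given atoms, in the given order."""
        idx = np.asarray(indices, dtype=int)
        kwargs = {f: getattr(self, f)[idx] for f in self._FIELDS}
        return Structure(coords=self.coords[idx], **kwargs)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        kwargs = {f: getattr(self, f) for f in self._FIELDS}
        return Structure(coords=np.asarray(coords, dtype=float), **kwargs)

    def residue_keys(self) -> list[tuple[str, int, str, str]]:
        """Unique (chain, resid, icode, resname) keys in atom order."""
        seen: dict[tuple[str, int, str, str], None] = {}
        for c, r, ic, rn in zip(self.chain, self.resid, self.icode, self.resname):
            seen.setdefault((str(c), int(r), str(ic), str(rn)), None)
        return list(seen)


class Trajectory:
    """Constant-topology trajectory: one :class:`Structure` of identities
    plus an F x N x 3 coordinate array in Å."""

    def __init__(self, topology: Structure, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("trajectory coords must be F x N x 3")
        if coords.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coords have {coords.shape[1]} atoms per frame but topology has {topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.topology = topology
        self.coords = coords

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    @classmethod
    def from_structure(cls, struct: Structure) -> "Trajectory":
        return cls(struct, struct.coords[None])


# -----------------------------------------------------------------------------
# Selection mini-language
# -----------------------------------------------------------------------------

_KEYWORDS = {
    "and", "or", "not", "(", ")",
    "chain", "resid", "resname", "name", "element", "serial",
    "protein", "hetero", "hydrogen", "backbone", "all", "none",
}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    """Recursive-descent parser evaluating directly to a boolean mask."""

    def __init__(self, tokens: list[str], struct: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = struct

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        if self.peek() == "not":
            self.next()
            return ~self.unary()
        return self.primary()

    def primary(self) -> np.ndarray:
        tok = self.next()
        n = self.s.n_atoms
        if tok == "(":
            mask = self.or_expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "protein":
            return ~self.s.hetero & np.isin(self.s.resname, list(_STANDARD_AA))
        if tok == "hetero":
            return self.s.hetero.copy()
        if tok == "hydrogen":
            return self.s.element == "H"
        if tok == "backbone":
            prot = ~self.s.hetero & np.isin(self.s.resname, list(_STANDARD_AA))
            return prot & np.isin(self.s.name, list(_BACKBONE_NAMES - {"OXT"}))
        if tok == "chain":
            return np.isin(self.s.chain, self._values(tok))
        if tok == "resname":
            return np.isin(self.s.resname, self._values(tok))
        if tok == "name":
            return np.isin(self.s.name, self._values(tok))
        if tok == "element":
            return np.isin(self.s.element, [v.upper() for v in self._values(tok)])
        if tok in ("resid", "serial"):
            arr = self.s.resid if tok == "resid" else self.s.serial
            mask = np.zeros(n, dtype=bool)
            for val in self._values(tok):
                if "-" in val[1:]:  # allow a leading minus sign
                    cut = val.index("-", 1)
                    lo, hi = val[:cut], val[cut + 1:]
                    try:
                        lo_i, hi_i = int(lo), int(hi)
                    except ValueError:
                        raise SelectionError(f"bad {tok} range {val!r}") from None
                    mask |= (arr >= lo_i) & (arr <= hi_i)
                else:
                    try:
                        mask |= arr == int(val)
                    except ValueError:
                        raise SelectionError(f"bad {tok} value {val!r}") from None
            return mask
        raise SelectionError(f"unknown selection token {tok!r}")

    def _values(self, keyword: str) -> list[str]:
        """Consume one or more value tokens (comma- or space-separated)."""
        vals: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS:
                break
            self.next()
            vals.extend(v for v in tok.split(",") if v)
        if not vals:
            raise SelectionError(f"keyword {keyword!r} requires at least one value")
        return vals


@dataclass(frozen=True)
class AtomSelection:
    """A selection expression; resolves to a deterministic ordered index list."""

    expression: str

    def indices(self, struct: Structure) -> np.ndarray:
        return select(struct, self)

    def mask(self, struct: Structure) -> np.ndarray:
        return _SelParser(_tokenize(self.expression), struct).parse()


def select(struct: Structure, sel: AtomSelection | str) -> np.ndarray:
    """Resolve a selection on a structure to indices in topology order.

    An empty result is allowed but triggers a warning, since it usually
    means a typo in a residue name or chain id.
    """
    if isinstance(sel, str):
        sel = AtomSelection(sel)
    mask = sel.mask(struct)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {sel.expression!r} matched no atoms", stacklevel=2)
    return idx


# -----------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# -----------------------------------------------------------------------------

_ELEMENT_TWO = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA", "SE", "CU", "NI", "CO", "CD"}


def _infer_element(atom_name: str, resname: str = "") -> str:
    """PDB-convention element inference for records with a blank element column."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    # Two-letter elements are only trusted for non-amino-acid residues or ions;
    # in amino acids "CA" is a carbon, "CD" a carbon, etc.
    if two in _ELEMENT_TWO and resname not in _STANDARD_AA:
        return two.capitalize().upper()
    return stripped[0].upper()


def _precheck_models(path: Path) -> None:
    """Scan the raw file so frame-count errors can name the offending model
    and coordinate errors the offending line."""
    counts: dict[int, int] = {}
    model = 0
    n_atom_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    model = int(line[6:].split()[0])
                except (IndexError, ValueError):
                    model += 1
            elif rec in ("ATOM  ", "HETATM"):
                n_atom_records += 1
                counts[model] = counts.get(model, 0) + 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi]
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise PDBFormatError(
                            f"{path}: unparseable coordinate field {fieldtxt!r} on line {lineno}"
                        ) from None
    if n_atom_records == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    if len(counts) > 1:
        ref_model, ref_n = next(iter(counts.items()))
        for m, n in counts.items():
            if n != ref_n:
                raise PDBFormatError(
                    f"{path}: MODEL {m} has {n} atom records but MODEL {ref_model} has {ref_n}"
                )


def read_pdb(path) -> Trajectory:
    """Read a (multi-model) PDB file as a trajectory.

    ``MODEL``/``ENDMDL`` blocks become frames; a single-model file yields a
    one-frame trajectory.  HETATM records are retained and flagged via the
    ``hetero`` field.  For duplicated altlocs the highest-occupancy record is
    kept (the first on a tie).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    _precheck_models(path)
    pdbf = PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # biotite warns on guessed elements
        stack = pdbf.get_structure(
            model=None,
            altloc="occupancy",
            extra_fields=["atom_id", "occupancy", "b_factor"],
        )
    arr0 = stack[0]
    n = arr0.array_length()
    element = np.asarray(arr0.element, dtype="U2")
    blank = element == ""
    if np.any(blank):
        names = np.asarray(arr0.atom_name)
        resnames = np.asarray(arr0.res_name)
        element = element.copy()
        for i in np.flatnonzero(blank):
            element[i] = _infer_element(str(names[i]), str(resnames[i]))
    topology = Structure(
        serial=np.asarray(arr0.atom_id, dtype=int),
        name=np.asarray(arr0.atom_name, dtype="U6"),
        element=element,
        resname=np.asarray(arr0.res_name, dtype="U5"),
        resid=np.asarray(arr0.res_id, dtype=int),
        icode=np.asarray(arr0.ins_code, dtype="U1"),
        chain=np.asarray(arr0.chain_id, dtype="U4"),
        altloc=np.full(n, "", dtype="U1"),
        occupancy=np.asarray(arr0.occupancy, dtype=float),
        bfactor=np.asarray(arr0.b_factor, dtype=float),
        hetero=np.asarray(arr0.hetero, dtype=bool),
        coords=np.asarray(arr0.coord, dtype=float),
    )
    return Trajectory(topology, np.asarray(stack.coord, dtype=float))


_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def _to_biotite(struct: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(struct.n_atoms)
    arr.coord = np.asarray(struct.coords, dtype=np.float32)
    arr.chain_id = struct.chain.astype("U4")
    arr.res_id = struct.resid
    arr.ins_code = struct.icode.astype("U1")
    arr.res_name = struct.resname.astype("U5")
    arr.hetero = struct.hetero
    arr.atom_name = struct.name.astype("U6")
    arr.element = struct.element.astype("U2")
    arr.set_annotation("atom_id", struct.serial)
    arr.set_annotation("occupancy", struct.occupancy)
    arr.set_annotation("b_factor", struct.bfactor)
    return arr


def write_pdb(traj: Trajectory | Structure, path, *, force_model_records: bool = False) -> None:
    """Write a trajectory (or single structure) as a fixed-width PDB file.

    One ``MODEL`` block is written per frame; a one-frame trajectory is
    written without MODEL records unless ``force_model_records`` is set.
    """
    if isinstance(traj, Structure):
        traj = Trajectory.from_structure(traj)
    if traj.n_frames < 1:
        raise PDBFormatError("cannot write an empty trajectory")
    c = traj.coords
    if c.max() > _PDB_COORD_MAX or c.min() < _PDB_COORD_MIN:
        raise PDBFormatError(
            "coordinates exceed the PDB fixed-width column range "
            f"[{_PDB_COORD_MIN}, {_PDB_COORD_MAX}]"
        )
    arr = _to_biotite(traj.topology)
    pdbf = PDBFile()
    if traj.n_frames == 1 and not force_model_records:
        arr.coord = np.asarray(traj.coords[0], dtype=np.float32)
        pdbf.set_structure(arr)
        pdbf.write(str(path))
        return
    stack = bst.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdbf.set_structure(stack)
    pdbf.write(str(path))
    if traj.n_frames == 1:
        # biotite omits MODEL records for a single-model stack; add them
        text = Path(path).read_text()
        if "MODEL" not in text:
            Path(path).write_text("MODEL        1\n" + text.rstrip("\n") + "\nENDMDL\n")
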