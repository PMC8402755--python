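"""Macromolecular structure I/O and a uniform atom-selection data model.

Structures are held in a deliberately small hierarchy (:class:`StructureModel`
-> chains -> :class:`Residue` -> :class:`Atom`) that preserves author residue
numbering — the single coordinate system used throughout the package (for PFV
PR-RT this is 1..751 spanning PR through RNase H).  Parsing of PDB and mmCIF
files is delegated to :mod:`gemmi`; writing is fixed-column PDB v3.3.

Conventions applied package-wide:

* alternate locations are kept, but all downstream geometry uses the
  highest-occupancy conformer (ties broken by altloc letter, so 'A' wins);
* hydrogens are ignored — deposited models at ~3 Å resolution carry none and
  every analysis here is heavy-atom;
* waters are excluded from polymer chains and from hetero sites unless a
  selection explicitly asks for them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

try:  # 3-to-1 letter codes for model_sequence
    from Bio.Data.IUPACData import protein_letters_3to1_extended as _3TO1
except ImportError:  # pragma: no cover
    _3TO1 = {}

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_BACKBONE_NAMES = {"N", "CA", "C", "O"}


class StructureParseError(ValueError):
    """Raised when a file cannot be parsed as a structure."""


class StructureFormatError(ValueError):
    """Raised for an unknown or unsupported structure format."""


class SelectionError(ValueError):
    """Raised for malformed atom selections."""


@dataclass
class Atom:
    """One heavy (or explicitly requested) atom.

    Coordinates are in Å.  ``alt_loc`` is a single character or '' and
    ``is_primary`` marks the conformer kept for downstream geometry.
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""
    is_hetero: bool = False
    is_primary: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")
        self.element = self.element.strip().upper()


@dataclass
class Residue:
    """A residue addressed by author number plus insertion code."""

    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name and a.is_primary:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return _3TO1.get(self.name.capitalize(), "X") if len(self.name) == 3 else "X"


#: Flat atom reference: (chain id, residue, atom).
AtomRef = tuple[str, Residue, Atom]


class AtomGroup:
    """A flat, ordered list of ``(chain_id, residue, atom)`` references.

    Order is deterministic: chain, then residue number/insertion code, then
    atom record order within the residue.
    """

    def __init__(self, refs: Iterable[AtomRef] = ()):  # noqa: D107
        self.refs: list[AtomRef] = list(refs)

    def __len__(self) -> int:
        return len(self.refs)

    def __iter__(self) -> Iterator[AtomRef]:
        return iter(self.refs)

    def __add__(self, other: "AtomGroup") -> "AtomGroup":
        return AtomGroup(self.refs + other.refs)

    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in Å."""
        if not self.refs:
            return np.empty((0, 3))
        return np.array([a.coords for _, _, a in self.refs])

    def elements(self) -> list[str]:
        return [a.element for _, _, a in self.refs]

    def residue_ids(self) -> list[tuple[str, int, str]]:
        return [(c, r.number, r.insertion_code) for c, r, _ in self.refs]

    def n_residues(self) -> int:
        return len({(c, id(r)) for c, r, _ in self.refs})


@dataclass
class StructureModel:
    """Hierarchical chain/residue/atom model of one structure.

    ``chains`` maps chain id to an ordered residue list; ``hetero_sites``
    holds ions/ligands (never waters unless requested at parse time) apart
    from the polymer; ``seqres`` optionally carries per-chain full-construct
    sequences from the file header.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    hetero_sites: list[tuple[str, Atom]] = field(default_factory=list)
    seqres: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            seen = set()
            for r in residues:
                key = (cid, r.number, r.insertion_code)
                if key in seen:
                    raise ValueError(f"duplicate residue {key} in model {self.id!r}")
                seen.add(key)

    # -- basic queries -----------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def first_chain(self) -> str:
        if not self.chains:
            raise ValueError(f"model {self.id!r} has no polymer chains")
        return next(iter(self.chains))

    def residue(self, chain: str, number: int, insertion_code: str = "") -> Residue:
        for r in self.chains.get(chain, []):
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"residue {chain}:{number}{insertion_code} not in model {self.id!r}")

    def n_polymer_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    def n_atoms(self) -> int:
        n = sum(len(r.atoms) for rs in self.chains.values() for r in rs)
        return n + len(self.hetero_sites)

    def all_atoms(self, primary_only: bool = True) -> AtomGroup:
        refs: list[AtomRef] = []
        for cid, residues in self.chains.items():
            for r in residues:
                for a in r.atoms:
                    if primary_only and not a.is_primary:
                        continue
                    refs.append((cid, r, a))
        return AtomGroup(refs)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    """Declarative atom selection.

    ``ranges`` is a list of ``(chain_id | None, start, end)`` with inclusive
    author-numbered bounds; ``None`` chain means every chain.  With no ranges
    the whole polymer is selected.
    """

    ranges: list[tuple[str | None, int, int]] = field(default_factory=list)
    chains: list[str] | None = None
    heavy_only: bool = True
    polymer_only: bool = True

    @classmethod
    def parse(cls, spec: str) -> "Selection":
        """Parse e.g. ``"A:450-590,A:593-751"`` or ``"10-99"``."""
        ranges: list[tuple[str | None, int, int]] = []
        for token in spec.split(","):
            token = token.strip()
            if not token:
                continue
            chain: str | None = None
            if ":" in token:
                chain, token = token.split(":", 1)
                chain = chain.strip()
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", token.strip())
            if not m:
                raise SelectionError(f"cannot parse selection token {token!r}")
            start = int(m.group(1))
            end = int(m.group(2)) if m.group(2) else start
            ranges.append((chain, start, end))
        return cls(ranges=ranges)

    def validate(self) -> None:
        for chain, start, end in self.ranges:
            if start > end:
                raise SelectionError(f"range start {start} > end {end} (chain {chain or '*'})")


def select_atoms(model: StructureModel, selection: Selection | str | None = None) -> AtomGroup:
    """Resolve a :class:`Selection` against a model into an :class:`AtomGroup`.

    Ranges are inclusive on both ends in author numbering; order of the
    result is deterministic (chain, residue, atom record order).  An empty
    selection result is allowed.
    """
    if selection is None:
        selection = Selection()
    elif isinstance(selection, str):
        selection = Selection.parse(selection)
    selection.validate()

    refs: list[AtomRef] = []
    for cid, residues in model.chains.items():
        if selection.chains is not None and cid not in selection.chains:
            continue
        for r in residues:
            if selection.ranges:
                hit = any(
                    (chain is None or chain == cid) and start <= r.number <= end
                    for chain, start, end in selection.ranges
                )
                if not hit:
                    continue
            for a in r.atoms:
                if not a.is_primary:
                    continue
                if selection.heavy_only and a.element == "H":
                    continue
                refs.append((cid, r, a))
    if not selection.polymer_only:
        for name, atom in model.hetero_sites:
            if selection.heavy_only and atom.element == "H":
                continue
            hetres = Residue(number=0, name=name, atoms=[atom])
            refs.append(("*", hetres, atom))
    return AtomGroup(refs)


def model_sequence(model: StructureModel, chain: str | None = None, gap_char: str = "-") -> str:
    """One-letter sequence of the modeled chain with gap marks at unmodeled numbers.

    The string spans min..max observed author number; residues missing from
    the model appear as ``gap_char``; unknown residue names map to 'X'.
    """
    chain = chain or model.first_chain()
    if chain not in model.chains:
        raise KeyError(f"chain {chain!r} not in model {model.id!r}")
    residues = model.chains[chain]
    if not residues:
        return ""
    by_number = {r.number: r for r in residues}
    lo, hi = min(by_number), max(by_number)
    return "".join(by_number[i].one_letter if i in by_number else gap_char for i in range(lo, hi + 1))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _flag_primary_conformers(residue: Residue) -> None:
    # group altlocs by atom name; keep highest occupancy, ties -> lowest altloc letter
    groups: dict[str, list[Atom]] = {}
    for a in residue.atoms:
        groups.setdefault(a.name, []).append(a)
    for atoms in groups.values():
        best = min(atoms, key=lambda a: (-a.occupancy, a.alt_loc or "A"))
        for a in atoms:
            a.is_primary = a is best


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of a multi-model file is taken.  Author numbering is
    preserved; waters are dropped; non-water HETATM entities go to
    ``hetero_sites``.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt not in {"pdb", "mmcif", "cif", "auto"}:
        raise StructureFormatError(f"unknown structure format {format!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in {"mmcif", "cif"}:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with record context
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")
    gmodel = st[0]

    model = StructureModel(id=st.name or path.stem)
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            is_het = gres.het_flag == "H"
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name or "X",
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=ga.b_iso,
                    alt_loc=ga.altloc if ga.altloc != "\x00" else "",
                    is_hetero=is_het,
                )
                for ga in gres
            ]
            if is_het and not _is_amino(gres.name):
                for a in atoms:
                    model.hetero_sites.append((gres.name, a))
                continue
            res = Residue(
                number=gres.seqid.num,
                name=gres.name,
                atoms=atoms,
                insertion_code=gres.seqid.icode.strip(),
            )
            _flag_primary_conformers(res)
            residues.append(res)
        if residues:
            model.chains[gchain.name] = residues

    # SEQRES / entity sequences, when the header carries them
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            seq = gemmi.one_letter_code(ent.full_sequence).upper()
            for cid in ent.subchains or []:
                model.seqres.setdefault(cid, seq)
            for cid in model.chains:
                model.seqres.setdefault(cid, seq)
    return model


def _is_amino(resname: str) -> bool:
    return resname.capitalize() in _3TO1


# ---------------------------------------------------------------------------
# Writing (fixed-column PDB v3.3)
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, record: str, name: str, alt: str, resname: str,
                   chain: str, resnum: int, icode: str, atom: Atom) -> str:
    if len(chain) != 1:
        raise ValueError(f"chain id {chain!r} not representable in fixed-column PDB")
    if abs(resnum) > 9999 or serial > 99999:
        raise ValueError("residue/atom number overflows PDB fixed columns")
    x, y, z = atom.coords
    if max(abs(x), abs(y), abs(z)) >= 10000:
        raise ValueError("coordinate overflows PDB fixed columns")
    # atom-name column convention: 1/2-letter elements right-packed
    if len(name) < 4 and len(atom.element) == 1:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_f}{alt or ' ':1s}{resname:>3s} {chain}"
        f"{resnum:>4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          {atom.element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "pdb", remarks: Sequence[str] = ()) -> Path:
    """Write a model as fixed-column PDB; the file re-parses to an equal model."""
    if format.lower() != "pdb":
        raise StructureFormatError(f"unsupported output format {format!r}")
    path = Path(path)
    lines = [f"HEADER    {model.id[:40]:<40s}"]
    for rem in remarks:
        lines.append(f"REMARK 999 {rem}"[:80])
    serial = 0
    for cid, residues in model.chains.items():
        for r in residues:
            for a in r.atoms:
                serial += 1
                rec = "HETATM" if a.is_hetero else "ATOM"
                lines.append(_pdb_atom_line(serial, rec, a.name, a.alt_loc, r.name,
                                            cid, r.number, r.insertion_code, a))
        if residues:
            serial += 1
            last = residues[-1]
            lines.append(f"TER   {serial:>5d}      {last.name:>3s} {cid}{last.number:>4d}")
    het_serial = serial
    for idx, (name, a) in enumerate(model.hetero_sites, start=1):
        het_serial += 1
        lines.append(_pdb_atom_line(het_serial, "HETATM", a.name, a.alt_loc, name,
                                    "X", idx, "", a))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def models_close(a: StructureModel, b: StructureModel, tol: float = 1e-3) -> bool:
    """True when two models agree in topology and coordinates to ``tol`` Å."""
    if list(a.chains) != list(b.chains) or len(a.hetero_sites) != len(b.hetero_sites):
        return False
    for cid in a.chains:
        ra, rb = a.chains[cid], b.chains[cid]
        if len(ra) != len(rb):
            return False
        for x, y in zip(ra, rb):
            if (x.number, x.insertion_code, x.name) != (y.number, y.insertion_code, y.name):
                return False
            if len(x.atoms) != len(y.atoms):
                return False
            for ax, ay in zip(x.atoms, y.atoms):
                if ax.name != ay.name or ax.element != ay.element:
                    return False
                if not np.allclose(ax.coords, ay.coords, atol=tol):
                    return False
    for (na, aa), (nb, ab) in zip(a.hetero_sites, b.hetero_sites):
        if na != nb or not np.allclose(aa.coords, ab.coords, atol=tol):
            return False
    return True
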