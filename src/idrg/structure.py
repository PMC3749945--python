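"""Structure I/O: uniform in-memory model of multi-chain complexes.

Reads PDB / mmCIF files (via gemmi) into a light-weight chain/residue/atom
hierarchy tailored to the needs of the Rg/N classifier and the interface
analysis: one coordinate model, alternate locations resolved to the highest
occupancy, waters dropped, common modified residues mapped to their parent
amino acid, and hetero ligands kept but flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ComplexPartition",
    "StructureParseError",
    "read_structure",
    "partition_complex",
    "write_pdb",
    "STANDARD_AA",
    "MODIFIED_AA_PARENT",
    "THREE_TO_ONE",
]

#: The 20 standard amino-acid three-letter codes.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Common chemically modified residues mapped to their parent amino acid.
#: Chains made of such residues are still polypeptide for the purpose of
#: counting residues with coordinates.
MODIFIED_AA_PARENT = {
    "MSE": "MET",  # selenomethionine
    "FME": "MET",
    "CSO": "CYS",
    "CSD": "CYS",
    "OCS": "CYS",
    "CME": "CYS",
    "SEC": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "HYP": "PRO",
    "MLY": "LYS",
    "M3L": "LYS",
    "KCX": "LYS",
    "LLP": "LYS",
    "PCA": "GLU",
    "HIC": "HIS",
    "NEP": "HIS",
    "MLE": "LEU",
    "AIB": "ALA",
    "ABA": "ALA",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATERS = {"HOH", "DOD", "WAT"}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read or is empty."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_id: str  # author residue number + insertion code, e.g. "100" or "100A"
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    is_standard_aa: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def has_ca(self) -> bool:
        return self.atom("CA") is not None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def n_observed(self) -> int:
        """Number of standard amino-acid residues with a CA atom present."""
        return sum(1 for r in self.residues if r.is_standard_aa and r.has_ca())

    def is_polymer(self) -> bool:
        return self.n_observed >= 1

    def ca_coords(self) -> np.ndarray:
        """(n_observed, 3) α-carbon coordinates, in residue order."""
        coords = [r.atom("CA").coord for r in self.residues if r.is_standard_aa and r.has_ca()]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if r.is_standard_aa and r.has_ca())

    def iter_standard(self) -> Iterator[Residue]:
        for r in self.residues:
            if r.is_standard_aa:
                yield r


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.id}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.id}: no chain {chain_id!r}")

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_polymer()]


@dataclass
class ComplexPartition:
    """One chain singled out as the candidate segment, everything else as one
    rigid binding-partner group."""

    segment: Chain
    partner: list[Chain]

    def __post_init__(self) -> None:
        if not self.partner:
            raise ValueError("partition requires a non-empty partner group")
        if any(c.chain_id == self.segment.chain_id for c in self.partner):
            raise ValueError("segment chain cannot also be a partner")

    def swapped(self) -> "ComplexPartition":
        """Partition with sides exchanged (only valid for two-chain complexes)."""
        if len(self.partner) != 1:
            raise ValueError("swap is only defined for a single partner chain")
        return ComplexPartition(segment=self.partner[0], partner=[self.segment])


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: the highest occupancy, first encountered on ties."""
    best: dict[str, Atom] = {}
    for a in atoms:
        cur = best.get(a.name)
        if cur is None or a.occupancy > cur.occupancy:
            best[a.name] = a
    # preserve original order
    seen: set[int] = set()
    out = []
    for a in atoms:
        chosen = best[a.name]
        if id(chosen) not in seen and chosen is a:
            seen.add(id(chosen))
            out.append(a)
    return out


def read_structure(path: str | Path, format: str | None = None, model_index: int = 0) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Structure file. Format is inferred from the extension unless ``format``
        (``"pdb"`` or ``"mmcif"``) is given.
    model_index
        Which coordinate model to read (0-based). Multi-model NMR files
        default to the first model.

    Notes
    -----
    Waters are discarded. Alternate locations are resolved to the highest
    occupancy conformer (first wins on ties). Modified residues listed in
    :data:`MODIFIED_AA_PARENT` are renamed to their parent and treated as
    standard; other HETATM entities are retained with ``is_hetero=True`` and
    do not count toward ``n_observed``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if format == "pdb" or (format is None and path.suffix.lower() in {".pdb", ".ent"}):
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif" or (format is None and path.suffix.lower() in {".cif", ".mmcif"}):
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no coordinate models")
    if model_index >= len(st):
        raise StructureParseError(f"{path}: model {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip()
            if name in _WATERS:
                continue
            parent = MODIFIED_AA_PARENT.get(name, name)
            is_std = parent in STANDARD_AA
            het = gres.het_flag == "H" and not is_std
            atoms = []
            for ga in gres:
                if not math.isfinite(ga.pos.x):
                    continue
                atoms.append(
                    Atom(
                        name=ga.name.strip(),
                        element=ga.element.name.upper(),
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        is_hetero=het,
                    )
                )
            if not atoms:
                continue
            seq_id = str(gres.seqid.num) + (gres.seqid.icode.strip() if gres.seqid.icode else "")
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_id=seq_id,
                    res_name=parent if is_std else name,
                    atoms=_resolve_altlocs(atoms),
                    is_standard_aa=is_std,
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise StructureParseError(f"{path}: structure contains no residues")
    return StructureModel(id=path.stem, chains=chains, model_index=model_index)


def partition_complex(model: StructureModel, segment_chain: str) -> ComplexPartition:
    """Split a complex into one candidate segment chain vs. the union of all
    other polymer chains as a rigid binding partner.

    Raises ``ValueError`` if the structure has no second polymer chain (a
    segment must interact with at least one partner).
    """
    segment = model.chain(segment_chain)
    partner = [c for c in model.polymer_chains() if c.chain_id != segment_chain]
    if not partner:
        raise ValueError(f"{model.id}: chain {segment_chain} has no binding partner")
    return ComplexPartition(segment=segment, partner=partner)


def _pdb_atom_line(serial: int, atom: Atom, res: Residue, hetero: bool) -> str:
    name = atom.name
    # PDB column rules: element symbols of one letter start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    record = "HETATM" if hetero else "ATOM  "
    seq = res.seq_id
    icode = " "
    if seq and seq[-1].isalpha():
        icode = seq[-1]
        seq = seq[:-1]
    x, y, z = atom.coord
    return (
        f"{record}{serial:>5d} {name:<4s}{'':1s}{res.res_name:>3s} {res.chain_id[:1]:1s}"
        f"{int(seq):>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(model: StructureModel, path: str | Path, remarks: Sequence[str] = ()) -> None:
    """Write the model as a minimal standards-conforming PDB file."""
    lines: list[str] = [f"REMARK 999 {r}" for r in remarks]
    serial = 1
    for chain in model.chains:
        last_res = None
        for res in chain.residues:
            for atom in res.atoms:
                hetero = atom.is_hetero and not res.is_standard_aa
                lines.append(_pdb_atom_line(serial, atom, res, hetero))
                serial += 1
            last_res = res
        if last_res is not None and not last_res.atoms[0].is_hetero:
            lines.append(f"TER   {serial:>5d}      {last_res.res_name:>3s} {chain.chain_id[:1]}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
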