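"""Inter-chain salt bridges, hydrogen bonds, and intra-chain disulfides.

Salt bridges follow a purely geometric rule: any side-chain donor nitrogen
(ARG NE/NH1/NH2, LYS NZ, HIS ND1/NE2) paired with a side-chain acceptor
oxygen (ASP OD1/OD2, GLU OE1/OE2) across the interface at a distance below
4.0 Å, with chain-terminal amine/carboxylate groups optionally included.
Hydrogen bonds use distance-plus-angle criteria with hydrogens placed by
ideal geometry on backbone amides where possible; aromatic-ring acceptors
are not considered. Disulfides are CYS SG–SG pairs within 2.5 Å, greedily
matched nearest-first so each SG joins at most one bond.

Neighbor search uses a KD-tree at the cutoff radius; its output is
contractually identical to exhaustive all-pairs enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Chain, ComplexPartition, Residue

__all__ = [
    "AtomRef",
    "SaltBridge",
    "HydrogenBond",
    "DisulfideBond",
    "ContactSummary",
    "HBondCriteria",
    "find_salt_bridges",
    "find_hbonds",
    "find_disulfides",
    "summarize_contacts",
]

# side-chain salt-bridge donors (nitrogens of basic groups)
_SB_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
# side-chain salt-bridge acceptors (oxygens of acidic groups)
_SB_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# hydrogen-bond donor heavy atoms per residue type (side chains), with the
# bonded "antecedent" atom used for the fallback angle criterion
_HB_DONORS = {
    "SER": (("OG", "CB"),),
    "THR": (("OG1", "CB"),),
    "TYR": (("OH", "CZ"),),
    "ASN": (("ND2", "CG"),),
    "GLN": (("NE2", "CD"),),
    "HIS": (("ND1", "CG"), ("NE2", "CD2")),
    "TRP": (("NE1", "CD1"),),
    "LYS": (("NZ", "CE"),),
    "ARG": (("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")),
    "CYS": (("SG", "CB"),),
}
# hydrogen-bond acceptors per residue type (side chains), with antecedent
_HB_ACCEPTORS = {
    "ASP": (("OD1", "CG"), ("OD2", "CG")),
    "GLU": (("OE1", "CD"), ("OE2", "CD")),
    "ASN": (("OD1", "CG"),),
    "GLN": (("OE1", "CD"),),
    "SER": (("OG", "CB"),),
    "THR": (("OG1", "CB"),),
    "TYR": (("OH", "CZ"),),
    "HIS": (("ND1", "CG"), ("NE2", "CD2")),
    "MET": (("SD", "CG"),),
    "CYS": (("SG", "CB"),),
}


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    seq_id: str
    res_name: str
    atom_name: str


@dataclass
class SaltBridge:
    donor: AtomRef
    acceptor: AtomRef
    distance: float


@dataclass
class HydrogenBond:
    donor: AtomRef
    acceptor: AtomRef
    d_DA: float
    d_HA: float | None
    angle_DHA: float | None


@dataclass
class DisulfideBond:
    sg_a: AtomRef
    sg_b: AtomRef
    distance: float


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    A donor/acceptor heavy-atom pair is a hydrogen bond when d(D,A) ≤
    ``max_da`` and — if a hydrogen could be placed on the donor by ideal
    geometry — the D-H···A angle is at least ``min_dha_angle``; otherwise
    the fallback requires the angle at the donor between its bonded heavy
    atom and the acceptor to be at least ``min_fallback_angle``.
    """

    max_da: float = 3.9
    min_dha_angle: float = 90.0
    min_fallback_angle: float = 90.0


def _chain_termini(chain: Chain) -> tuple[Residue | None, Residue | None]:
    std = [r for r in chain.residues if r.is_standard_aa]
    if not std:
        return None, None
    return std[0], std[-1]


def _collect_sb_atoms(chains: list[Chain], include_termini: bool, include_his: bool):
    donors: list[tuple[AtomRef, np.ndarray]] = []
    acceptors: list[tuple[AtomRef, np.ndarray]] = []
    for chain in chains:
        nterm, cterm = _chain_termini(chain)
        for res in chain.residues:
            if not res.is_standard_aa:
                continue
            for name in _SB_DONORS.get(res.res_name, ()):
                if res.res_name == "HIS" and not include_his:
                    continue
                atom = res.atom(name)
                if atom is not None:
                    donors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, name), atom.coord))
            for name in _SB_ACCEPTORS.get(res.res_name, ()):
                atom = res.atom(name)
                if atom is not None:
                    acceptors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, name), atom.coord))
            if include_termini:
                if res is nterm:
                    atom = res.atom("N")
                    if atom is not None:
                        donors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, "N"), atom.coord))
                if res is cterm:
                    for name in ("O", "OXT"):
                        atom = res.atom(name)
                        if atom is not None:
                            acceptors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, name), atom.coord))
    return donors, acceptors


def _cross_pairs(
    donors: list[tuple[AtomRef, np.ndarray]],
    acceptors: list[tuple[AtomRef, np.ndarray]],
    segment_id: str,
    cutoff: float,
):
    """Donor/acceptor index pairs across the segment/partner divide within
    ``cutoff`` (strict), via KD-tree."""
    if not donors or not acceptors:
        return
    d_coords = np.vstack([c for _, c in donors])
    a_coords = np.vstack([c for _, c in acceptors])
    tree = cKDTree(a_coords)
    for i, (dref, dc) in enumerate(donors):
        for j in tree.query_ball_point(dc, cutoff):
            aref = acceptors[j][0]
            d_side = dref.chain_id == segment_id
            a_side = aref.chain_id == segment_id
            if d_side == a_side:
                continue
            dist = float(np.linalg.norm(dc - a_coords[j]))
            if dist < cutoff:
                yield dref, aref, dist


def find_salt_bridges(
    partition: ComplexPartition,
    cutoff: float = 4.0,
    include_termini: bool = True,
    include_his: bool = True,
) -> list[SaltBridge]:
    """All cross-interface donor-N / acceptor-O atom pairs closer than
    ``cutoff`` (strict inequality). Pairs, not residues, are counted."""
    chains = [partition.segment] + list(partition.partner)
    donors, acceptors = _collect_sb_atoms(chains, include_termini, include_his)
    out = [
        SaltBridge(donor=d, acceptor=a, distance=dist)
        for d, a, dist in _cross_pairs(donors, acceptors, partition.segment.chain_id, cutoff)
    ]
    out.sort(key=lambda b: (b.donor.chain_id, b.donor.seq_id, b.donor.atom_name, b.acceptor.chain_id, b.acceptor.seq_id, b.acceptor.atom_name))
    return out


def _place_amide_h(res: Residue, prev_c: np.ndarray | None) -> np.ndarray | None:
    """Ideal backbone amide hydrogen: on the bisector of C(i−1)–N and CA–N,
    1.0 Å from N. PRO has no amide H."""
    if res.res_name == "PRO" or prev_c is None:
        return None
    n = res.atom("N")
    ca = res.atom("CA")
    if n is None or ca is None:
        return None
    u1 = n.coord - prev_c
    u2 = n.coord - ca.coord
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        return None
    direction = u1 / n1 + u2 / n2
    norm = np.linalg.norm(direction)
    if norm == 0:
        return None
    return n.coord + direction / norm


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _collect_hb_atoms(chains: list[Chain]):
    """Donor and acceptor heavy atoms with their geometric context."""
    donors = []  # (ref, coord, h_coord or None, antecedent coord or None)
    acceptors = []  # (ref, coord)
    for chain in chains:
        std = [r for r in chain.residues if r.is_standard_aa]
        for i, res in enumerate(std):
            prev_c = std[i - 1].atom("C").coord if i > 0 and std[i - 1].atom("C") else None
            n = res.atom("N")
            if n is not None:
                h = _place_amide_h(res, prev_c)
                ca = res.atom("CA")
                donors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, "N"), n.coord, h, ca.coord if ca else None))
            for name, ante in _HB_DONORS.get(res.res_name, ()):
                atom = res.atom(name)
                if atom is not None:
                    ante_atom = res.atom(ante)
                    donors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, name), atom.coord, None, ante_atom.coord if ante_atom else None))
            o = res.atom("O")
            if o is not None:
                acceptors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, "O"), o.coord))
            oxt = res.atom("OXT")
            if oxt is not None:
                acceptors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, "OXT"), oxt.coord))
            for name, _ante in _HB_ACCEPTORS.get(res.res_name, ()):
                atom = res.atom(name)
                if atom is not None:
                    acceptors.append((AtomRef(chain.chain_id, res.seq_id, res.res_name, name), atom.coord))
    return donors, acceptors


def find_hbonds(partition: ComplexPartition, criteria: HBondCriteria = HBondCriteria()) -> list[HydrogenBond]:
    """Cross-interface hydrogen bonds under the geometric criteria.

    Donor–acceptor self-pairs within one residue never arise because only
    cross-chain pairs are considered.
    """
    chains = [partition.segment] + list(partition.partner)
    donors, acceptors = _collect_hb_atoms(chains)
    if not donors or not acceptors:
        return []
    a_coords = np.vstack([c for _, c in acceptors])
    tree = cKDTree(a_coords)
    seg = partition.segment.chain_id
    out: list[HydrogenBond] = []
    for dref, dc, h, ante in donors:
        for j in tree.query_ball_point(dc, criteria.max_da):
            aref = acceptors[j][0]
            if (dref.chain_id == seg) == (aref.chain_id == seg):
                continue
            ac = a_coords[j]
            d_da = float(np.linalg.norm(dc - ac))
            if d_da > criteria.max_da:
                continue
            if h is not None:
                ang = _angle(dc, h, ac)
                if ang < criteria.min_dha_angle:
                    continue
                out.append(HydrogenBond(dref, aref, d_da, float(np.linalg.norm(h - ac)), ang))
            else:
                if ante is not None and _angle(ante, dc, ac) < criteria.min_fallback_angle:
                    continue
                out.append(HydrogenBond(dref, aref, d_da, None, None))
    out.sort(key=lambda b: (b.donor.chain_id, b.donor.seq_id, b.donor.atom_name, b.acceptor.chain_id, b.acceptor.seq_id, b.acceptor.atom_name))
    return out


def find_disulfides(chain: Chain, cutoff: float = 2.5) -> list[DisulfideBond]:
    """CYS SG–SG pairs within ``cutoff`` Å, greedily matched nearest-first;
    each SG participates in at most one bond."""
    sgs: list[tuple[AtomRef, np.ndarray]] = []
    for res in chain.residues:
        if res.res_name == "CYS":
            atom = res.atom("SG")
            if atom is not None:
                sgs.append((AtomRef(chain.chain_id, res.seq_id, "CYS", "SG"), atom.coord))
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    bonds = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(DisulfideBond(sg_a=sgs[i][0], sg_b=sgs[j][0], distance=d))
    return bonds


@dataclass
class ContactSummary:
    n_salt_bridges: int
    n_hbonds: int
    interface_area: float
    salt_bridges_per_100: float
    hbonds_per_100: float


def summarize_contacts(
    bridges: list[SaltBridge], hbonds: list[HydrogenBond], interface_area: float
) -> ContactSummary:
    """Raw counts plus per-100-Å² normalization by the interface area."""
    if interface_area <= 0:
        if bridges or hbonds:
            raise ValueError("nonzero contacts with zero interface area")
        return ContactSummary(0, 0, 0.0, 0.0, 0.0)
    return ContactSummary(
        n_salt_bridges=len(bridges),
        n_hbonds=len(hbonds),
        interface_area=interface_area,
        salt_bridges_per_100=len(bridges) / (interface_area / 100.0),
        hbonds_per_100=len(hbonds) / (interface_area / 100.0),
    )
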