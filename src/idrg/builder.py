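"""Ideal-geometry peptide construction.

Builds extended polypeptides by placing standard backbone geometry with the
natural extension of reference frames (NeRF) and grafting heavy-atom residue
templates from the chemical component dictionary onto each backbone frame.
Used for the Gly-X-Gly reference tripeptides and for synthetic fixtures.
Geometry is idealized (bond lengths/angles from standard peptide values,
φ = ψ = ω = 180° unless stated); it is meant to be geometrically sound, not
energy-minimized.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as _ccd_info

from .structure import Atom, Chain, Residue, StructureModel

__all__ = [
    "residue_template",
    "build_peptide",
    "backbone_trace",
    "complete_ca_trace",
]

# standard backbone internal coordinates (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_A_N_CA_C = 111.0
_A_CA_C_N = 117.2
_A_C_N_CA = 121.7


@lru_cache(maxsize=32)
def residue_template(res_name: str) -> dict[str, np.ndarray]:
    """Heavy-atom ideal coordinates for a residue type, keyed by atom name.

    Sourced from the bundled chemical component dictionary; hydrogens are
    dropped. ``OXT`` is retained and only used at chain C-termini.
    """
    arr = _ccd_info.residue(res_name.upper())
    if arr is None:
        raise KeyError(f"no template for residue {res_name!r}")
    out: dict[str, np.ndarray] = {}
    for atom in arr:
        if atom.element == "H":
            continue
        out[atom.atom_name] = np.array(atom.coord, dtype=float)
    for required in ("N", "CA", "C"):
        if required not in out:
            raise KeyError(f"template {res_name}: missing backbone atom {required}")
    return out


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates
    (bond c–d, angle b–c–d, torsion a–b–c–d, angles in degrees)."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_trace(n_res: int, phi: float = 180.0, psi: float = 180.0, omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """N/CA/C positions for an ``n_res`` polypeptide at fixed dihedrals."""
    if n_res < 1:
        raise ValueError("need at least one residue")
    frames: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    frames.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = frames[-1]
        n = _place_nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place_nerf(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = _place_nerf(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        frames.append({"N": n, "CA": ca, "C": c})
    return frames


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation + translation minimizing RMSD of ``mobile`` onto ``target``.
    Returns (R, mobile_centroid, target_centroid)."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cm, ct


def build_peptide(
    sequence: list[str],
    chain_id: str = "A",
    phi: float = 180.0,
    psi: float = 180.0,
    start_seq_id: int = 1,
) -> Chain:
    """Build a full heavy-atom polypeptide in an idealized conformation.

    Each residue's template is rigidly superimposed (via its N/CA/C triad)
    onto the NeRF backbone, carrying carbonyl O and side chain along. OXT is
    kept only for the final residue.
    """
    frames = backbone_trace(len(sequence), phi=phi, psi=psi)
    residues: list[Residue] = []
    for i, (res_name, frame) in enumerate(zip(sequence, frames)):
        tpl = residue_template(res_name)
        mobile = np.vstack([tpl["N"], tpl["CA"], tpl["C"]])
        target = np.vstack([frame["N"], frame["CA"], frame["C"]])
        r, cm, ct = _kabsch(mobile, target)
        atoms = []
        for name, coord in tpl.items():
            if name == "OXT" and i != len(sequence) - 1:
                continue
            placed = (coord - cm) @ r.T + ct
            element = "".join(ch for ch in name if ch.isalpha())[0]
            if name.startswith("SE"):
                element = "SE"
            elif name[0].isdigit():
                element = name[1]
            atoms.append(Atom(name=name, element=element, coord=placed))
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_id=str(start_seq_id + i),
                res_name=res_name.upper(),
                atoms=atoms,
                is_standard_aa=True,
            )
        )
    return Chain(chain_id=chain_id, residues=residues)


def complete_ca_trace(
    ca_coords: np.ndarray,
    res_names: list[str] | None = None,
    chain_id: str = "A",
) -> Chain:
    """Decorate a bare CA trace with geometrically placed N, C, O atoms.

    The CA positions are preserved exactly (so CA-based Rg matches the
    designed trace); N and C are set along the local chain direction and O
    perpendicular to it. The result is a plausible backbone for SASA and
    contact calculations, not a stereochemically refined model.
    """
    ca = np.asarray(ca_coords, dtype=float)
    n_res = len(ca)
    if n_res < 1:
        raise ValueError("empty CA trace")
    if res_names is None:
        res_names = ["GLY"] * n_res
    residues: list[Residue] = []
    for i in range(n_res):
        u = _local_direction(ca, i)
        v = _perpendicular(u)
        n_pos = ca[i] - 1.46 * _unit(u + 0.55 * v)
        c_pos = ca[i] + 1.52 * _unit(u - 0.40 * v)
        o_pos = c_pos + 1.23 * v
        atoms = [
            Atom(name="N", element="N", coord=n_pos),
            Atom(name="CA", element="C", coord=ca[i]),
            Atom(name="C", element="C", coord=c_pos),
            Atom(name="O", element="O", coord=o_pos),
        ]
        residues.append(
            Residue(chain_id=chain_id, seq_id=str(i + 1), res_name=res_names[i], atoms=atoms, is_standard_aa=True)
        )
    return Chain(chain_id=chain_id, residues=residues)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _local_direction(ca: np.ndarray, i: int) -> np.ndarray:
    if len(ca) == 1:
        return np.array([1.0, 0.0, 0.0])
    if i == 0:
        return _unit(ca[1] - ca[0])
    if i == len(ca) - 1:
        return _unit(ca[-1] - ca[-2])
    return _unit(ca[i + 1] - ca[i - 1])


def _perpendicular(u: np.ndarray) -> np.ndarray:
    trial = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, trial))
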