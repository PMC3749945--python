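"""Solvent-accessible surface area and interface core/rim analysis.

SASA is computed with the Shrake–Rupley method: a deterministic
Fibonacci-spiral point set is scattered on each atom's solvent-expanded
sphere (van der Waals radius + probe radius, probe 1.4 Å) and the accessible
fraction is the fraction of points not buried inside any neighbouring
sphere. Hydrogens are ignored (crystal structures rarely resolve them);
heavy-atom radii follow the ProtOr convention, with CHARMM22 radii for
Zn²⁺, Ca²⁺ and Na⁺ ions.

The interface of a complex is the set of residues that lose SASA when the
binding partners associate. Each interface residue is classified after Levy
into core, rim or support by its relative SASA (rSASA) — SASA normalized by
the same residue type's SASA in an extended Gly-X-Gly tripeptide:

* rim:     rSASA > 0.25 in the complex;
* core:    rSASA ≤ 0.25 in the complex but > 0.25 in the free subunit;
* support: ≤ 0.25 in both states.

The interface area is the half-sum of the SASA buried on the two sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure.info as _ccd_info

from .builder import build_peptide
from .structure import Chain, ComplexPartition, Residue, THREE_TO_ONE

__all__ = [
    "RadiiTable",
    "SasaResult",
    "InterfaceResidue",
    "InterfaceSummary",
    "fibonacci_sphere",
    "shrake_rupley",
    "sasa_of_chains",
    "reference_gxg",
    "interface_map",
    "composition_profile",
    "enrichment",
    "FLEXIBILITY_ORDER",
    "DEFAULT_PROBE",
    "DEFAULT_N_POINTS",
]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: Amino acids ranked from order-promoting (rigid) to disorder-promoting
#: (flexible), the conventional x-axis ordering for composition profiles.
FLEXIBILITY_ORDER = list("WCFIYVLHMATRGQSNPDEK")

# CHARMM22 van der Waals radii (Rmin/2) for ions named in the radii table
_ION_RADII = {"ZN": 1.09, "CA": 1.367, "NA": 1.36375, "SOD": 1.36375, "CAL": 1.367}

# element fallbacks (Bondi-like) for atoms outside the ProtOr tables
_ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80, "F": 1.47, "CL": 1.75}


@dataclass
class RadiiTable:
    """Atom-class → van der Waals radius lookup (Å).

    ProtOr group radii for protein heavy atoms, CHARMM22 radii for Zn/Ca/Na
    ions, element-based fallback otherwise. ``overrides`` maps
    ``(res_name, atom_name)`` to explicit radii.
    """

    overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def radius(self, res_name: str, atom_name: str, element: str) -> float:
        key = (res_name.upper(), atom_name.upper())
        if key in self.overrides:
            return self.overrides[key]
        element = element.upper()
        if res_name.upper() in _ION_RADII and atom_name.upper() == res_name.upper():
            return _ION_RADII[res_name.upper()]
        r = _protor_radius(res_name.upper(), atom_name.upper())
        if r is not None:
            return r
        if element in _ELEMENT_RADII:
            return _ELEMENT_RADII[element]
        raise KeyError(f"no van der Waals radius for {res_name}/{atom_name} (element {element!r})")


@lru_cache(maxsize=4096)
def _protor_radius(res_name: str, atom_name: str) -> float | None:
    try:
        r = _ccd_info.vdw_radius_protor(res_name, atom_name)
    except Exception:
        return None
    return float(r) if r is not None else None


@dataclass
class SasaResult:
    """Per-atom and per-residue SASA for one calculation."""

    atom_sasa: np.ndarray  # (n_atoms,)
    atom_keys: list[tuple[str, str, str]]  # (chain_id, seq_id, atom_name)
    residue_sasa: dict[tuple[str, str], float]  # (chain_id, seq_id) -> Å²
    total: float
    probe_radius: float
    n_sphere_points: int


@lru_cache(maxsize=8)
def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly even distribution of ``n`` points on the unit
    sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def _collect_atoms(
    chains: list[Chain], radii: RadiiTable, include_hetero: bool
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, str]], list[tuple[str, str]]]:
    coords, rads, keys, res_keys = [], [], [], []
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                if atom.is_hetero and not include_hetero:
                    continue
                coords.append(atom.coord)
                rads.append(radii.radius(res.res_name, atom.name, atom.element))
                keys.append((chain.chain_id, res.seq_id, atom.name))
                res_keys.append((chain.chain_id, res.seq_id))
    if not coords:
        raise ValueError("no heavy atoms to compute SASA for")
    return np.asarray(coords), np.asarray(rads), keys, res_keys


def shrake_rupley(
    chains: list[Chain] | Chain,
    radii: RadiiTable | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_hetero: bool = False,
) -> SasaResult:
    """Shrake–Rupley SASA of a chain group (Å²).

    All chains passed in one call shade each other; to obtain the free-state
    SASA of a subunit, call again with only its chains.
    """
    if isinstance(chains, Chain):
        chains = [chains]
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    radii = radii or RadiiTable()
    coords, rads, keys, res_keys = _collect_atoms(chains, radii, include_hetero)
    sphere = fibonacci_sphere(n_points)

    expanded = rads + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    atom_sasa = np.empty(len(coords))
    for i in range(len(coords)):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + expanded.max()) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (expanded[nb] ** 2)[None, :], axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        atom_sasa[i] = 4.0 * np.pi * ri * ri * accessible / n_points

    residue_sasa: dict[tuple[str, str], float] = {}
    for rk, a in zip(res_keys, atom_sasa):
        residue_sasa[rk] = residue_sasa.get(rk, 0.0) + float(a)
    return SasaResult(
        atom_sasa=atom_sasa,
        atom_keys=keys,
        residue_sasa=residue_sasa,
        total=float(atom_sasa.sum()),
        probe_radius=probe,
        n_sphere_points=n_points,
    )


# alias used by callers that operate on whole-complex chain groups
sasa_of_chains = shrake_rupley


_GXG_CACHE: dict[tuple[float, int], dict[str, float]] = {}


def reference_gxg(
    radii: RadiiTable | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, float]:
    """SASA of residue X in an extended Gly-X-Gly tripeptide, for all 20
    standard residue types (Å²). Used to normalize residue SASA to rSASA."""
    cache_key = (probe, n_points)
    if radii is None and cache_key in _GXG_CACHE:
        return _GXG_CACHE[cache_key]
    table: dict[str, float] = {}
    for res_name in sorted(THREE_TO_ONE):
        chain = build_peptide(["GLY", res_name, "GLY"])
        result = shrake_rupley(chain, radii=radii, probe=probe, n_points=n_points)
        table[res_name] = result.residue_sasa[(chain.chain_id, "2")]
    if radii is None:
        _GXG_CACHE[cache_key] = table
    return table


@dataclass
class InterfaceResidue:
    chain_id: str
    seq_id: str
    res_name: str
    side: str  # "segment" or "partner"
    dsasa: float
    rsasa_bound: float
    rsasa_free: float
    region: str  # core / rim / support / none


@dataclass
class InterfaceSummary:
    interface_area: float  # Å², half-sum convention
    region_counts: dict[str, dict[str, int]]  # side -> region -> count
    composition: dict[str, dict[str, dict[str, float]]]  # side -> region -> aa -> fraction


def _assign_region(dsasa: float, rsasa_bound: float, rsasa_free: float, eps: float) -> str:
    if dsasa <= eps:
        return "none"
    if rsasa_bound > 0.25:
        return "rim"
    if rsasa_free > 0.25:
        return "core"
    return "support"


def interface_map(
    partition: ComplexPartition,
    radii: RadiiTable | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    eps: float = 0.1,
    include_hetero: bool = False,
) -> tuple[list[InterfaceResidue], InterfaceSummary]:
    """ΔSASA interface definition with Levy core/rim classification.

    Three SASA runs under one configuration: the whole complex, the segment
    alone, and the partner group alone. Per residue,
    ``dsasa = SASA_free − SASA_bound``; residues with dsasa > ``eps`` are
    interface residues; the interface area is half the summed dsasa over
    both sides.
    """
    radii = radii or RadiiTable()
    all_chains = [partition.segment] + list(partition.partner)
    bound = shrake_rupley(all_chains, radii, probe, n_points, include_hetero)
    free_seg = shrake_rupley([partition.segment], radii, probe, n_points, include_hetero)
    free_par = shrake_rupley(list(partition.partner), radii, probe, n_points, include_hetero)
    ref = reference_gxg(None if radii == RadiiTable() else radii, probe, n_points)

    free_by_res = dict(free_seg.residue_sasa)
    free_by_res.update(free_par.residue_sasa)
    side_of = {partition.segment.chain_id: "segment"}
    side_of.update({c.chain_id: "partner" for c in partition.partner})

    residues: list[InterfaceResidue] = []
    total_dsasa = 0.0
    for chain in all_chains:
        for res in chain.residues:
            key = (chain.chain_id, res.seq_id)
            if key not in bound.residue_sasa:
                continue
            sasa_b = bound.residue_sasa[key]
            sasa_f = free_by_res.get(key, sasa_b)
            dsasa = sasa_f - sasa_b
            total_dsasa += max(dsasa, 0.0)
            if not res.is_standard_aa:
                continue
            ref_area = ref.get(res.res_name)
            if ref_area is None or ref_area <= 0:
                continue
            rb = sasa_b / ref_area
            rf = sasa_f / ref_area
            residues.append(
                InterfaceResidue(
                    chain_id=chain.chain_id,
                    seq_id=res.seq_id,
                    res_name=res.res_name,
                    side=side_of[chain.chain_id],
                    dsasa=dsasa,
                    rsasa_bound=rb,
                    rsasa_free=rf,
                    region=_assign_region(dsasa, rb, rf, eps),
                )
            )

    interface_area = 0.5 * total_dsasa
    region_counts: dict[str, dict[str, int]] = {"segment": {}, "partner": {}}
    composition: dict[str, dict[str, dict[str, float]]] = {"segment": {}, "partner": {}}
    for side in ("segment", "partner"):
        for region in ("core", "rim", "support"):
            members = [r for r in residues if r.side == side and r.region == region]
            region_counts[side][region] = len(members)
            if members:
                composition[side][region] = composition_profile([r.res_name for r in members])
    return residues, InterfaceSummary(
        interface_area=interface_area, region_counts=region_counts, composition=composition
    )


def composition_profile(res_names: list[str]) -> dict[str, float]:
    """Amino-acid composition as fractions summing to 1, keyed by one-letter
    code and ordered by the flexibility ranking."""
    if not res_names:
        raise ValueError("empty residue set")
    counts = {aa: 0 for aa in FLEXIBILITY_ORDER}
    n = 0
    for name in res_names:
        one = THREE_TO_ONE.get(name, None) if len(name) == 3 else name
        if one in counts:
            counts[one] += 1
            n += 1
    if n == 0:
        raise ValueError("no standard amino acids in residue set")
    return {aa: counts[aa] / n for aa in FLEXIBILITY_ORDER}


def enrichment(profile_a: dict[str, float], profile_b: dict[str, float]) -> dict[str, float]:
    """Per-type composition difference (A − B), in flexibility order."""
    return {aa: profile_a.get(aa, 0.0) - profile_b.get(aa, 0.0) for aa in FLEXIBILITY_ORDER}
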