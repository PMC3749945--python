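"""Synthetic structure fixtures with known geometry.

Emulates the chain classes that the Rg/N classifier separates — extended
(rod-like) traces, ideal α-helices, random walks, and collapsed globules
rescaled to a target Flory law Rg = R0·N^ν — plus small designed complexes
with interfaces of known burial and contact geometry. Every stochastic kind
is seeded and the seed is written into the emitted PDB header, so fixture
generation is fully reproducible.

Fixture geometry is designed, not energy-minimized: it gives exact control
over Rg, burial, and contact distances at the price of physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .builder import build_peptide, complete_ca_trace, residue_template, _kabsch
from .rg import radius_of_gyration
from .structure import Atom, Chain, ComplexPartition, Residue, StructureModel, write_pdb

__all__ = [
    "FixtureSpec",
    "ca_trace",
    "make_chain",
    "make_binary_complex",
    "ToyComplexRecipe",
    "ChainRecipe",
    "ResidueRecipe",
    "DesignedContact",
    "make_toy_complex",
    "salt_bridge_recipe",
    "separated_pair_recipe",
    "buried_leucine_recipe",
    "beta_bridge_recipe",
    "save_fixture",
]

KINDS = ("extended", "helix", "random_walk", "globule")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chain.

    d is the CA-CA spacing for extended/random-walk chains (3.8 Å, the
    trans-peptide virtual bond). Helices use the ideal α-helix parameters
    (1.5 Å rise, 2.3 Å radius, 100°/residue). Globules are isotropic point
    clouds rescaled so that Rg = R0·N^ν exactly.
    """

    kind: str
    N: int
    seed: int = 0
    d: float = 3.8
    helix_rise: float = 1.5
    helix_radius: float = 2.3
    helix_twist_deg: float = 100.0
    globule_R0: float = 2.2
    globule_nu: float = 0.35
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.d <= 0 or self.helix_rise <= 0 or self.helix_radius <= 0 or self.globule_R0 <= 0:
            raise ValueError("geometry parameters must be positive")


def ca_trace(spec: FixtureSpec) -> np.ndarray:
    """Bare CA coordinates (N, 3) realizing the designed geometry."""
    n = spec.N
    if spec.kind == "extended":
        return np.column_stack([spec.d * np.arange(n), np.zeros(n), np.zeros(n)])
    if spec.kind == "helix":
        t = np.deg2rad(spec.helix_twist_deg) * np.arange(n)
        return np.column_stack(
            [spec.helix_radius * np.cos(t), spec.helix_radius * np.sin(t), spec.helix_rise * np.arange(n)]
        )
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "random_walk":
        steps = rng.normal(size=(n - 1, 3)) if n > 1 else np.empty((0, 3))
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        steps = spec.d * steps / np.where(norms == 0, 1.0, norms)
        return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    # globule: isotropic cloud rescaled to the target Flory law
    pts = rng.normal(size=(n, 3))
    pts -= pts.mean(axis=0)
    target = spec.globule_R0 * n**spec.globule_nu
    current = radius_of_gyration(pts)
    if current == 0:
        raise ValueError("degenerate globule: zero radius of gyration")
    return pts * (target / current)


def make_chain(spec: FixtureSpec) -> StructureModel:
    """Build one synthetic chain as a structure model.

    The CA coordinates realize the designed geometry exactly; N, C and O
    backbone atoms are added around the trace so SASA and contact code see
    full backbones.
    """
    ca = ca_trace(spec)
    chain = complete_ca_trace(ca, chain_id=spec.chain_id)
    return StructureModel(id=f"{spec.kind}_{spec.N}_{spec.seed}", chains=[chain])


def make_binary_complex(
    segment_spec: FixtureSpec,
    partner_spec: FixtureSpec,
    gap: float = 5.0,
) -> StructureModel:
    """Segment chain next to a partner chain, separated along +y by the two
    bounding radii plus ``gap`` (no designed contacts; used for batch
    classification fixtures)."""
    if segment_spec.chain_id == partner_spec.chain_id:
        partner_spec = FixtureSpec(**{**partner_spec.__dict__, "chain_id": "B"})
    seg = make_chain(segment_spec).chains[0]
    par = make_chain(partner_spec).chains[0]
    seg_coords = np.vstack([a.coord for r in seg.residues for a in r.atoms])
    par_coords = np.vstack([a.coord for r in par.residues for a in r.atoms])
    shift = np.array(
        [0.0, seg_coords[:, 1].max() - par_coords[:, 1].min() + gap, 0.0]
    )
    for res in par.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + shift
    return StructureModel(
        id=f"cx_{segment_spec.kind}{segment_spec.N}_{partner_spec.kind}{partner_spec.N}_{segment_spec.seed}",
        chains=[seg, par],
    )


# ---------------------------------------------------------------------------
# designed toy complexes


@dataclass
class ResidueRecipe:
    res_name: str
    atoms: dict[str, tuple[float, float, float]]


@dataclass
class ChainRecipe:
    chain_id: str
    residues: list[ResidueRecipe]


@dataclass
class DesignedContact:
    """A distance constraint the emitted complex must satisfy to ±0.01 Å."""

    atom_a: tuple[str, str, str]  # (chain_id, seq_id, atom_name)
    atom_b: tuple[str, str, str]
    distance: float


@dataclass
class ToyComplexRecipe:
    name: str
    chains: list[ChainRecipe]
    contacts: list[DesignedContact] = field(default_factory=list)


_ELEMENT_OF = {"N": "N", "O": "O", "S": "S", "C": "C"}


def _element_for(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return _ELEMENT_OF.get(ch, ch)
    return "C"


def make_toy_complex(recipe: ToyComplexRecipe) -> StructureModel:
    """Materialize a designed complex and verify its distance constraints."""
    chains = []
    for cr in recipe.chains:
        residues = []
        for i, rr in enumerate(cr.residues):
            atoms = [
                Atom(name=name, element=_element_for(name), coord=np.asarray(xyz, dtype=float))
                for name, xyz in rr.atoms.items()
            ]
            residues.append(
                Residue(chain_id=cr.chain_id, seq_id=str(i + 1), res_name=rr.res_name, atoms=atoms, is_standard_aa=True)
            )
        chains.append(Chain(chain_id=cr.chain_id, residues=residues))
    model = StructureModel(id=recipe.name, chains=chains)
    for contact in recipe.contacts:
        a = model.chain(contact.atom_a[0])
        b = model.chain(contact.atom_b[0])
        atom_a = next(r for r in a.residues if r.seq_id == contact.atom_a[1]).atom(contact.atom_a[2])
        atom_b = next(r for r in b.residues if r.seq_id == contact.atom_b[1]).atom(contact.atom_b[2])
        if atom_a is None or atom_b is None:
            raise ValueError(f"{recipe.name}: designed contact references a missing atom")
        d = float(np.linalg.norm(atom_a.coord - atom_b.coord))
        if abs(d - contact.distance) > 0.01:
            raise ValueError(
                f"{recipe.name}: contact {contact.atom_a}–{contact.atom_b} is {d:.3f} Å, designed {contact.distance}"
            )
    return model


def _placed_residue(
    res_name: str,
    origin: np.ndarray,
    toward: np.ndarray,
    align: tuple[str, str] | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Template residue translated so its CA sits at ``origin``.

    Orientation: the vector between the two atoms named in ``align``
    (default CA → side-chain tip) is rotated onto ``toward``.
    """
    tpl = residue_template(res_name)
    ca = tpl["CA"]
    if align is None:
        tip_name = {"LYS": "NZ", "GLU": "OE1", "LEU": "CD1", "ARG": "NH1", "ASP": "OD1"}.get(res_name, "CB")
        a, b = ca, tpl.get(tip_name, ca + np.array([1.0, 0.0, 0.0]))
    else:
        a, b = tpl[align[0]], tpl[align[1]]
    v = b - a
    toward = np.asarray(toward, dtype=float)
    mobile = np.vstack([np.zeros(3), v])
    target = np.vstack([np.zeros(3), np.linalg.norm(v) * toward / np.linalg.norm(toward)])
    r, cm, ct = _kabsch(mobile, target)
    return {name: tuple((coord - ca - cm) @ r.T + ct + origin) for name, coord in tpl.items() if name != "OXT"}


def salt_bridge_recipe(distance: float = 3.5) -> ToyComplexRecipe:
    """Single LYS chain facing a single GLU chain with the NZ–OE1 pair at
    the designed distance (and no other donor/acceptor pair in range)."""
    lys = _placed_residue("LYS", origin=np.zeros(3), toward=np.array([1.0, 0.0, 0.0]))
    nz = np.asarray(lys["NZ"])
    # orient the glutamate by its CD→OE1 bond so OE2 points off-axis, away
    # from the donor, then translate OE1 onto the designed separation
    glu = _placed_residue(
        "GLU", origin=np.zeros(3), toward=np.array([-1.0, 0.0, 0.0]), align=("CD", "OE1")
    )
    oe1 = np.asarray(glu["OE1"])
    offset = nz + np.array([distance, 0.0, 0.0]) - oe1
    glu = {name: tuple(np.asarray(xyz) + offset) for name, xyz in glu.items()}
    return ToyComplexRecipe(
        name=f"toy_saltbridge_{distance:.2f}",
        chains=[
            ChainRecipe("A", [ResidueRecipe("LYS", lys)]),
            ChainRecipe("B", [ResidueRecipe("GLU", glu)]),
        ],
        contacts=[DesignedContact(("A", "1", "NZ"), ("B", "1", "OE1"), distance)],
    )


def separated_pair_recipe(gap: float = 20.0) -> ToyComplexRecipe:
    """Two single-GLY chains with at least ``gap`` Å between any atom pair —
    a no-interface control."""
    gly_a = _placed_residue("GLY", origin=np.zeros(3), toward=np.array([1.0, 0.0, 0.0]))
    gly_b = _placed_residue("GLY", origin=np.array([gap + 10.0, 0.0, 0.0]), toward=np.array([1.0, 0.0, 0.0]))
    return ToyComplexRecipe(
        name=f"toy_separated_{gap:.0f}",
        chains=[
            ChainRecipe("A", [ResidueRecipe("GLY", gly_a)]),
            ChainRecipe("B", [ResidueRecipe("GLY", gly_b)]),
        ],
    )


def buried_leucine_recipe() -> ToyComplexRecipe:
    """GLY-LEU-GLY segment whose central leucine side chain is enclosed by a
    cage of partner glycines: the leucine is solvent-exposed in the free
    segment but buried in the complex (interface core)."""
    seg_chain = build_peptide(["GLY", "LEU", "GLY"], chain_id="A")
    seg_residues = []
    for res in seg_chain.residues:
        seg_residues.append(ResidueRecipe(res.res_name, {a.name: tuple(a.coord) for a in res.atoms}))
    leu = seg_chain.residues[1]
    side_atoms = [leu.atom(n) for n in ("CB", "CG", "CD1", "CD2") if leu.atom(n) is not None]
    center = np.mean([a.coord for a in side_atoms], axis=0)
    ca = leu.atom("CA").coord
    outward = center - ca
    outward /= np.linalg.norm(outward)
    # glycine shell on a sphere around the side-chain centroid, leaving free
    # only the hemisphere facing back into the segment backbone
    rng = np.random.default_rng(7)
    cage: list[ResidueRecipe] = []
    shell_pts = []
    golden = np.pi * (3.0 - np.sqrt(5.0))
    n_shell = 26
    for i in range(n_shell):
        z = 1.0 - 2.0 * (i + 0.5) / n_shell
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * i
        u = np.array([rho * np.cos(theta), rho * np.sin(theta), z])
        if np.dot(u, outward) < -0.25:  # keep the backbone side open
            continue
        shell_pts.append(center + 4.9 * u)
    for pt in shell_pts:
        gly = _placed_residue("GLY", origin=pt, toward=pt - center)
        cage.append(ResidueRecipe("GLY", gly))
    return ToyComplexRecipe(
        name="toy_buried_leu",
        chains=[ChainRecipe("A", seg_residues), ChainRecipe("B", cage)],
    )


def beta_bridge_recipe(separation: float = 4.85) -> ToyComplexRecipe:
    """Two short antiparallel extended strands at β-sheet spacing, providing
    backbone N–H···O=C hydrogen bonds across the chain interface."""
    a = build_peptide(["ALA"] * 4, chain_id="A")
    b = build_peptide(["ALA"] * 4, chain_id="B")
    # flip strand B (rotate 180° about x) and shift it alongside strand A
    rot = np.diag([1.0, -1.0, -1.0])
    a_coords = np.vstack([at.coord for r in a.residues for at in r.atoms])
    for res in b.residues:
        for atom in res.atoms:
            atom.coord = atom.coord @ rot
    b_coords = np.vstack([at.coord for r in b.residues for at in r.atoms])
    shift = np.array(
        [a_coords[:, 0].mean() - b_coords[:, 0].mean(), separation + a_coords[:, 1].max() - b_coords[:, 1].max(), 0.0]
    )
    chains = []
    for chain, coords_shift in ((a, np.zeros(3)), (b, shift)):
        residues = []
        for res in chain.residues:
            residues.append(
                ResidueRecipe(res.res_name, {at.name: tuple(at.coord + coords_shift) for at in res.atoms})
            )
        chains.append(ChainRecipe(chain.chain_id, residues))
    return ToyComplexRecipe(name="toy_beta_bridge", chains=chains)


def save_fixture(model: StructureModel, path: str | Path, seed: int | None = None) -> None:
    """Write a fixture to PDB with its generation seed recorded in a REMARK."""
    remarks = ["synthetic fixture generated by idrg.fixtures"]
    if seed is not None:
        remarks.append(f"generation seed: {seed}")
    write_pdb(model, path, remarks=remarks)
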