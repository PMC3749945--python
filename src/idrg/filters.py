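"""Dataset-curation filters and redundancy removal.

A chain enters classification only if it has more than 20 residues with
coordinates, interacts with a partner chain of more than 70 residues, and is
not a small disulfide-stabilized domain (< 100 residues with ≥ 2 disulfide
bonds — such domains can be expanded yet folded and would contaminate the
negative set). Coiled-coil and transmembrane chains are excluded through
externally supplied chain lists rather than re-detected here.

Redundancy between chains is removed with the length-dependent sequence
identity threshold of Rost's HSSP curve; chains connected above the curve
are clustered and one representative (highest resolution, then longest,
then lexicographically first) is kept per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import find_disulfides
from .structure import StructureModel

__all__ = [
    "FilterConfig",
    "FilterReport",
    "ChainEntry",
    "apply_structure_filters",
    "rost_threshold",
    "sequence_identity",
    "redundancy_cluster",
]


@dataclass(frozen=True)
class FilterConfig:
    min_segment_len: int = 20
    min_partner_len: int = 70
    disulfide_len_cutoff: int = 100
    disulfide_min_bonds: int = 2
    rost_n: float = 3.0

    def __post_init__(self) -> None:
        if min(self.min_segment_len, self.min_partner_len, self.disulfide_len_cutoff, self.disulfide_min_bonds) <= 0:
            raise ValueError("filter parameters must be positive")


@dataclass
class FilterReport:
    """Per-chain pass/fail with the names of the rules that failed."""

    results: dict[str, tuple[bool, list[str]]] = field(default_factory=dict)

    def passed(self, chain_id: str) -> bool:
        return self.results[chain_id][0]

    def failing_rules(self, chain_id: str) -> list[str]:
        return self.results[chain_id][1]

    def passing_chains(self) -> list[str]:
        return [cid for cid, (ok, _) in self.results.items() if ok]


def apply_structure_filters(
    model: StructureModel,
    config: FilterConfig = FilterConfig(),
    external_exclusions: set[str] | list[str] = (),
) -> FilterReport:
    """Evaluate the curation rules for every polymer chain of a complex.

    ``external_exclusions`` holds chain identifiers (either bare chain ids
    or ``structure_id:chain_id``) flagged by external coiled-coil or
    transmembrane detection.
    """
    exclusions = set(external_exclusions)
    report = FilterReport()
    polymers = model.polymer_chains()
    for chain in polymers:
        failing: list[str] = []
        n = chain.n_observed
        if n <= config.min_segment_len:
            failing.append("min_segment_len")
        partner_lengths = [c.n_observed for c in polymers if c.chain_id != chain.chain_id]
        if not partner_lengths:
            failing.append("no_partner")
        elif max(partner_lengths) <= config.min_partner_len:
            failing.append("min_partner_len")
        if n < config.disulfide_len_cutoff:
            if len(find_disulfides(chain)) >= config.disulfide_min_bonds:
                failing.append("disulfide_rich")
        if chain.chain_id in exclusions or f"{model.id}:{chain.chain_id}" in exclusions:
            failing.append("external_exclusion")
        report.results[chain.chain_id] = (not failing, failing)
    return report


def rost_threshold(L: float, n: float = 3.0) -> float:
    """Length-dependent percent-identity threshold for homology (HSSP curve
    with exponential length correction), capped at 100%.

    ``n`` is the number of percentage points added above the default curve;
    ``L`` is the alignment length.
    """
    if L < 1:
        raise ValueError("alignment length must be at least 1")
    value = n + 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))
    return min(value, 100.0)


def sequence_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity and alignment length from a global alignment
    (BLOSUM62, gap open 10, gap extend 0.5 — Needle-style defaults).

    Identity is the number of identical aligned columns divided by the
    alignment length (gap columns included), as EMBOSS Needle reports it.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    length = len(a_row)
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return 100.0 * matches / length, length


@dataclass(frozen=True)
class ChainEntry:
    """One chain in the redundancy graph."""

    id: str
    length: int
    resolution: float = math.inf  # Å; lower is better


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def redundancy_cluster(
    entries: list[ChainEntry],
    identity: np.ndarray,
    aln_length: np.ndarray,
    config: FilterConfig = FilterConfig(),
) -> list[str]:
    """Cluster chains whose pairwise identity exceeds the Rost threshold and
    keep one representative per connected component.

    Parameters
    ----------
    entries
        Chain descriptors, index-aligned with the matrices.
    identity, aln_length
        Symmetric percent-identity and alignment-length matrices.

    Returns the sorted list of representative chain ids. The representative
    of a component is the entry with the best (lowest) resolution, ties
    broken by greater length, then lexicographic id.
    """
    n = len(entries)
    identity = np.asarray(identity, dtype=float)
    aln_length = np.asarray(aln_length)
    if identity.shape != (n, n) or not np.allclose(identity, identity.T):
        raise ValueError("identity matrix must be symmetric and match entries")
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if identity[i, j] > rost_threshold(float(aln_length[i, j]), config.rost_n):
                uf.union(i, j)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    reps = []
    for members in components.values():
        best = min(members, key=lambda k: (entries[k].resolution, -entries[k].length, entries[k].id))
        reps.append(entries[best].id)
    return sorted(reps)
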