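import numpy as np
import pytest

from idrg.builder import complete_ca_trace
from idrg.structure import Atom, Chain, Residue, StructureModel


@pytest.fixture(scope="session")
def gxg_reference():
    """Gly-X-Gly reference SASA table at moderate sphere resolution (shared
    across tests to avoid recomputation)."""
    from idrg.sasa import reference_gxg

    return reference_gxg(n_points=240)


def single_atom_chain(radius_key: str = "GLY", coord=(0.0, 0.0, 0.0), chain_id: str = "A") -> Chain:
    """A one-residue chain holding a single CA pseudo-atom (for SASA
    oracles with overridden radii)."""
    res = Residue(chain_id=chain_id, seq_id="1", res_name=radius_key,
                  atoms=[Atom("CA", "C", np.asarray(coord, dtype=float))], is_standard_aa=True)
    return Chain(chain_id=chain_id, residues=res and [res])


def chain_with_disulfides(n_res: int, n_bonds: int, chain_id: str = "A") -> Chain:
    """Extended glycine chain with ``n_bonds`` CYS pairs whose SG atoms sit
    2.04 Å apart (canonical disulfide length)."""
    ca = np.column_stack([3.8 * np.arange(n_res), np.zeros(n_res), np.zeros(n_res)])
    chain = complete_ca_trace(ca, chain_id=chain_id)
    for k in range(n_bonds):
        i, j = 2 * k, 2 * k + 1
        for idx in (i, j):
            chain.residues[idx].res_name = "CYS"
        sg_a = chain.residues[i].atom("CA").coord + np.array([0.0, 2.0, 0.0])
        sg_b = sg_a + np.array([2.04, 0.0, 0.0])
        chain.residues[i].atoms.append(Atom("SG", "S", sg_a))
        chain.residues[j].atoms.append(Atom("SG", "S", sg_b))
    return chain


def two_chain_model(chain_a: Chain, chain_b: Chain, model_id: str = "pair") -> StructureModel:
    return StructureModel(id=model_id, chains=[chain_a, chain_b])
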