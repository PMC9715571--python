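import numpy as np
import pytest

from xlassemble.structio import AtomRecord, StructureModel
from xlassemble.synthetic import make_docking_problem


def ca_model(chain_coords: dict, res_names=None, start_res=1) -> StructureModel:
    """Build a Calpha-only model from {chain_id: (N, 3) array}."""
    atoms = []
    for chain, coords in chain_coords.items():
        for i, p in enumerate(np.asarray(coords, float)):
            res = start_res + i
            name = "ALA"
            if res_names is not None:
                name = res_names.get((chain, res), "ALA")
            atoms.append(AtomRecord(chain, res, "", name, "CA", "C",
                                    (float(p[0]), float(p[1]), float(p[2]))))
    return StructureModel(atoms)


def pdb_line(serial, name, res_name, chain, res_seq, x, y, z,
             occ=1.0, b=0.0, element="C", altloc=" ", record="ATOM"):
    """One strictly column-aligned PDB coordinate record."""
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{res_name:>3} {chain}"
            f"{res_seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2}")


@pytest.fixture(scope="session")
def noiseless_problem():
    """A standard two-chain pose-recovery instance with exact crosslinks."""
    return make_docking_problem(seed=11)
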