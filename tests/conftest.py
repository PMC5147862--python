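import numpy as np
import pytest
from hypothesis import settings

from raseff.structure_io import Atom, ComplexStructure, Residue

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

_ATOM_NAMES = ("N", "CA", "C", "O", "CB")


def random_complex(rng: np.random.Generator, n_ras: int = 12, n_eff: int = 12,
                   box: float = 30.0) -> ComplexStructure:
    """Random two-chain complex with atoms scattered in a shared box, so
    inter-chain pairs straddle any contact cutoff."""

    def chain(chain_id: str, n: int) -> tuple[Residue, ...]:
        residues = []
        for i in range(n):
            center = rng.uniform(0, box, size=3)
            atoms = tuple(
                Atom(name=name, element=name[0],
                     coord=tuple(center + rng.uniform(-1.5, 1.5, size=3)))
                for name in _ATOM_NAMES
            )
            residues.append(Residue(chain_id=chain_id, number=i + 1, icode="",
                                    res_name="ALA", atoms=atoms))
        return tuple(residues)

    return ComplexStructure(structure_id="random", ras_chain=chain("A", n_ras),
                            effector_chain=chain("B", n_eff))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
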