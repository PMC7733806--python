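import numpy as np
import pytest

from pumpgeom.structure_io import Atom, Structure


def poly_ala_chain(n_res: int = 1000, chain: str = "A", seed: int = 0,
                   mainchain: bool = False) -> Structure:
    """Synthetic poly-alanine chain, Cα-only or full main chain, ~3.8 Å rise."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    for i in range(n_res):
        base = np.array([3.8 * i, 0.0, 0.0]) + rng.normal(scale=0.2, size=3)
        names = [("CA", "C")] if not mainchain else [
            ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        for j, (name, element) in enumerate(names):
            pos = base + np.array([0.4 * j, 0.3 * (j % 2), 0.0])
            atoms.append(Atom(serial=serial, name=name, altloc="", resname="ALA",
                              chain=chain, resseq=i + 1, icode="",
                              x=pos[0], y=pos[1], z=pos[2],
                              occupancy=1.0, element=element))
            serial += 1
    return Structure(atoms=atoms, source_id="POLYALA")


@pytest.fixture
def polyala():
    return poly_ala_chain()


@pytest.fixture
def polyala_mainchain():
    return poly_ala_chain(n_res=100, mainchain=True)
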