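import numpy as np
import pytest
from hypothesis import settings

from lipropen.lipid_model import LipidAtomPartition, LipidDefinition
from lipropen.structure_io import Atom, LipidInstance, ProteinChain, Residue

settings.register_profile("default", derandomize=True, max_examples=25)
settings.load_profile("default")


def diester_phosphoglyceride(chain_a: int = 16, chain_b: int = 18) -> LipidDefinition:
    """A hand-enumerated phosphatidylcholine-style lipid graph with two
    acyl chains of the given total carbon counts (carbonyl carbon
    included, so tails are chain_a-1 and chain_b-1 carbons)."""
    atoms = [
        ("C1G", "C"), ("C2G", "C"), ("C3G", "C"),          # glycerol
        ("P", "P"), ("O11", "O"), ("O12", "O"),            # phosphate
        ("O13", "O"), ("O14", "O"),
        ("C1C", "C"), ("C2C", "C"), ("N", "N"),            # choline
        ("C3C", "C"), ("C4C", "C"), ("C5C", "C"),
        ("O1E", "O"), ("CA0", "C"), ("OA0", "O"),          # sn-1 ester
        ("O2E", "O"), ("CB0", "C"), ("OB0", "O"),          # sn-2 ester
    ]
    bonds = [
        ("C1G", "C2G"), ("C2G", "C3G"),
        ("C3G", "O14"), ("O14", "P"), ("P", "O11"), ("P", "O12"), ("P", "O13"),
        ("O13", "C1C"), ("C1C", "C2C"), ("C2C", "N"),
        ("N", "C3C"), ("N", "C4C"), ("N", "C5C"),
        ("C1G", "O1E"), ("O1E", "CA0"), ("CA0", "OA0"),
        ("C2G", "O2E"), ("O2E", "CB0"), ("CB0", "OB0"),
    ]
    for prefix, carbonyl, n in (("A", "CA0", chain_a), ("B", "CB0", chain_b)):
        prev = carbonyl
        for k in range(1, n):
            atoms.append((f"{prefix}{k}", "C"))
            bonds.append((prev, f"{prefix}{k}"))
            prev = f"{prefix}{k}"
    return LipidDefinition("PCX", tuple(atoms), tuple(bonds))


def make_chain(residues: list[tuple[str, int, list[tuple[str, str, tuple]]]],
               structure_id: str = "test", chain_id: str = "A",
               resolution: float = 2.0, **kw) -> ProteinChain:
    """Build a ProteinChain from (name, seq_id, [(atom, element, xyz)])."""
    rs = tuple(
        Residue(name, seq, tuple(Atom(an, el, tuple(map(float, xyz))) for an, el, xyz in atoms))
        for name, seq, atoms in residues
    )
    return ProteinChain(structure_id, chain_id, rs, resolution, **kw)


def make_lipid(atoms: list[tuple[str, str, tuple]],
               head: set[str], tail: set[str],
               het_id: str = "ZZL", instance_id: str = "L_ZZL_1",
               bonds: tuple = ()) -> LipidInstance:
    """Build a LipidInstance with an explicit head/tail partition."""
    return LipidInstance(
        het_id, instance_id,
        tuple(Atom(an, el, tuple(map(float, xyz))) for an, el, xyz in atoms),
        LipidAtomPartition(het_id, frozenset(head), frozenset(tail)),
        tuple(bonds),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
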