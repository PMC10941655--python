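import numpy as np
import pytest

import specswitch as sw


@pytest.fixture
def helix10():
    return sw.make_helix(10)


@pytest.fixture
def two_partner():
    """Standard overlapping-footprint fixture: differential truth = 10..19."""
    spec = sw.FixtureSpec(
        seed=7, n_res_focal=50,
        partner_specs=[sw.PartnerSpec("B", (10, 25)), sw.PartnerSpec("C", (20, 40))])
    return sw.make_two_partner_fixture(spec)


@pytest.fixture
def two_partner_models(two_partner):
    c1, c2, truth = two_partner
    m1 = sw.ComplexModel("m1", c1, {"A": "shared_subunit", "B": "partner_specific"})
    m2 = sw.ComplexModel("m2", c2, {"A": "shared_subunit", "C": "partner_specific"})
    return m1, m2, truth


def random_structure(seed: int, n_atoms_a: int = 100, n_atoms_b: int = 100,
                     spread: float = 12.0) -> sw.Structure:
    """Random two-chain point cloud for contact-map oracle checks."""
    rng = np.random.default_rng(seed)

    def chain(cid, n):
        residues = []
        for i in range(n // 4):
            atoms = [sw.Atom(name, "C", rng.uniform(-spread, spread, 3))
                     for name in ("N", "CA", "C", "CB")]
            residues.append(sw.Residue(cid, i + 1, "ALA", atoms))
        return sw.Chain(cid, residues)

    return sw.Structure(f"rand{seed}", [chain("A", n_atoms_a), chain("B", n_atoms_b)])


def brute_force_contacts(structure: sw.Structure, chain_a: str, chain_b: str,
                         cutoff: float) -> set:
    """O(n^2) all-pairs contact oracle, independent of the k-d tree path."""
    out = {}
    for ra in structure.chain(chain_a).residues:
        for rb in structure.chain(chain_b).residues:
            dmin = min(
                float(np.linalg.norm(a.coords - b.coords))
                for a in ra.atoms if a.is_heavy
                for b in rb.atoms if b.is_heavy)
            if dmin <= cutoff:
                out[(ra.rid, rb.rid)] = dmin
    return out
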