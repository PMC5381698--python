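"""Typed contact detection, lock/interlock classification, mutation screen.

The oracle for contact detection is an exhaustive all-pairs scan applying the
same criteria tables, independent of the k-d-tree path.
"""

import itertools

import numpy as np
import pytest

from quatlock import detect_contacts, detect_interlock, mutate_in_silico_contact_check
from quatlock.interface_contacts import (
    AtomRef,
    ContactCriteria,
    _classify_pair,
    _order_pair,
)
from quatlock.structure_io import Assembly, Atom, Chain, RegionDefinition, Residue
from quatlock.synthetic_data import (
    copy_assembly,
    make_assembly,
    make_subunit,
    plant_contact,
    set_residue_type,
)


def _residue(chain_id, seq, name, atom_specs):
    atoms = [
        Atom(serial=i + 1, name=an, element=an[0], coords=np.array(xyz, dtype=float))
        for i, (an, xyz) in enumerate(atom_specs)
    ]
    return Residue(chain_id=chain_id, seq_num=seq, res_name=name, atoms=atoms)


def _arg_asp_pair(distance):
    """Arg guanidinium NH1 placed `distance` Å from Asp carboxylate OD1."""
    arg = _residue(
        "A", 10, "ARG",
        [("N", (0, 0, 0)), ("CA", (1.5, 0, 0)), ("C", (3, 0, 0)), ("O", (3.5, 1, 0)),
         ("CB", (1.5, 1.5, 0)), ("NH1", (1.5, 3.0, 0))],
    )
    asp = _residue(
        "B", 50, "ASP",
        [("N", (20, 0, 0)), ("CA", (21.5, 0, 0)), ("C", (23, 0, 0)), ("O", (23.5, 1, 0)),
         ("CB", (21.5, 1.5, 0)), ("OD1", (1.5, 3.0 + distance, 0))],
    )
    return Assembly(
        id="pair",
        chains=[Chain("A", [arg]), Chain("B", [asp])],
    )


def test_planted_arg_asp_gives_hbond_and_salt_bridge():
    asm = _arg_asp_pair(2.9)
    records = detect_contacts(asm)
    types = {r.contact_type for r in records if r.atom_a.atom_name == "NH1" or r.atom_b.atom_name == "NH1"}
    assert {"hbond", "salt_bridge"} <= types
    sb = [r for r in records if r.contact_type == "salt_bridge"]
    assert sb[0].distance == pytest.approx(2.9)
    assert sb[0].scope == "inter_chain"


def test_pair_beyond_cutoffs_gives_nothing():
    asm = _arg_asp_pair(4.2)
    records = detect_contacts(asm)
    assert not [r for r in records if r.contact_type in ("hbond", "salt_bridge")
                and {"NH1", "OD1"} & {r.atom_a.atom_name, r.atom_b.atom_name}]


def test_duplicate_pairs_emitted_once_and_ordered():
    asm = _arg_asp_pair(2.9)
    records = detect_contacts(asm)
    keys = [(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in records]
    assert len(keys) == len(set(keys))
    for r in records:
        assert r.atom_a.key() <= r.atom_b.key()


def brute_force_contacts(assembly, criteria=None):
    """O(n²) all-pairs oracle with the same typing tables."""
    criteria = criteria or ContactCriteria()
    atoms = []
    for chain in assembly.chains:
        for res in chain.protein_residues():
            for atom in res.atoms:
                if atom.element != "H":
                    atoms.append((AtomRef(chain.chain_id, res.seq_num, res.res_name, atom.name), atom.coords))
    out = set()
    for (ra, ca), (rb, cb) in itertools.combinations(atoms, 2):
        if (ra.chain_id, ra.seq_num) == (rb.chain_id, rb.seq_num):
            continue
        d = float(np.linalg.norm(ca - cb))
        if d <= 0:
            continue
        for ctype in _classify_pair(ra, rb, d, criteria):
            a, b = _order_pair(ra, rb)
            out.add((a.key(), b.key(), ctype))
    return out


def test_matches_all_pairs_oracle_on_random_assembly(rng):
    # ~50-atom toy assembly of random Arg/Asp/Leu residues in a tight box
    res_types = {
        "ARG": ["N", "CA", "C", "O", "CB", "NE", "NH1"],
        "ASP": ["N", "CA", "C", "O", "CB", "OD1", "OD2"],
        "LEU": ["N", "CA", "C", "O", "CB", "CD1"],
    }
    chains = []
    for cid in "AB":
        residues = []
        for seq in range(1, 5):
            name = list(res_types)[int(rng.integers(3))]
            base = rng.uniform(0, 12, 3)
            specs = [(an, base + rng.uniform(-1.5, 1.5, 3)) for an in res_types[name]]
            residues.append(_residue(cid, seq, name, [(a, tuple(c)) for a, c in specs]))
        chains.append(Chain(cid, residues))
    asm = Assembly(id="rand", chains=chains)
    impl = {(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in detect_contacts(asm)}
    assert impl == brute_force_contacts(asm)


def test_contacts_invariant_under_rigid_motion(c4_assembly):
    from scipy.spatial.transform import Rotation

    asm, truth = c4_assembly
    planted = plant_contact(asm, 7, 27, 2.9, truth=truth)
    base = {(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in detect_contacts(planted)}
    moved = copy_assembly(planted)
    R = Rotation.from_euler("xyz", [1.0, -0.5, 2.2]).as_matrix()
    for _, _, atom in moved.all_atoms():
        atom.coords = R @ atom.coords + np.array([11.0, -4.0, 6.0])
    assert {(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in detect_contacts(moved)} == base


def test_cutoff_monotonicity(c4_assembly):
    asm, truth = c4_assembly
    planted = plant_contact(asm, 7, 27, 3.3, truth=truth)
    tight = detect_contacts(planted, ContactCriteria(3.0, 3.5, 4.0))
    loose = detect_contacts(planted, ContactCriteria(3.5, 4.0, 4.5))
    tight_keys = {(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in tight}
    loose_keys = {(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in loose}
    assert tight_keys <= loose_keys


# ---------------------------------------------------------------------------
# Interlock classification


@pytest.fixture(scope="module")
def planted_c4():
    subunit = make_subunit(seed=1, n_residues=30)
    asm, truth = make_assembly(subunit, "Cn", 4)
    return plant_contact(asm, region_seq=7, partner_seq=27, distance=2.9, truth=truth), truth


def test_c4_planted_contact_classified_interlock(planted_c4):
    asm, _ = planted_c4
    region = RegionDefinition("binding", ((5, 9),))
    report = detect_interlock(asm, region)
    assert report.classification == "interlock"
    assert (7, 27) in report.recurring_pairs
    assert not report.asymmetric_chains
    # the planted pair recurs once per chain
    planted_pairs = [p for p in report.partner_pairs if p[0][1] == 7 and p[1][1] == 27]
    assert len(planted_pairs) == 4
    assert all(a[0] != b[0] for a, b in planted_pairs)  # all inter-chain


def test_monomer_long_range_contact_classified_lock():
    chain = make_subunit(seed=9, n_residues=40)
    asm = Assembly(id="mono", chains=[chain])
    planted = plant_contact(asm, region_seq=7, partner_seq=37, distance=2.9,
                            chain_map={"A": "A"})
    region = RegionDefinition("binding", ((5, 9),))
    report = detect_interlock(planted, region, min_seq_separation=20)
    assert report.classification == "lock"


def test_lock_requires_sequence_separation():
    chain = make_subunit(seed=9, n_residues=40)
    asm = Assembly(id="mono", chains=[chain])
    planted = plant_contact(asm, region_seq=7, partner_seq=37, distance=2.9,
                            chain_map={"A": "A"})
    region = RegionDefinition("binding", ((5, 9),))
    report = detect_interlock(planted, region, min_seq_separation=35)
    # 30-residue separation no longer qualifies as tertiary stabilization
    assert report.classification == "none"


def test_asymmetric_chain_listed(planted_c4):
    asm, _ = planted_c4
    broken = copy_assembly(asm)
    # push chain D's partner segment away so its planted pair vanishes
    for res in broken.chain("A").residues:
        if abs(res.seq_num - 27) <= 2:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([0.0, 0.0, 25.0])
    region = RegionDefinition("binding", ((5, 9),))
    report = detect_interlock(broken, region)
    # chain D's region pairs with chain A's segment, now displaced
    assert "D" in report.asymmetric_chains


def test_region_unresolved_everywhere_errors(planted_c4):
    asm, _ = planted_c4
    region = RegionDefinition("nowhere", ((500, 510),))
    with pytest.raises(ValueError):
        detect_interlock(asm, region)


# ---------------------------------------------------------------------------
# In-silico substitution screen


def test_truncating_arg_abolishes_planted_salt_bridge(planted_c4):
    asm, _ = planted_c4
    delta = mutate_in_silico_contact_check(asm, [("A", 7, "LEU")])
    assert any(r.contact_type == "salt_bridge" for r in delta)
    for rec in delta:
        assert rec.involves("A", 7)


def test_substitution_at_contact_free_residue_empty(planted_c4):
    asm, _ = planted_c4
    delta = mutate_in_silico_contact_check(asm, [("A", 15, "GLY")])
    assert delta == []


def test_double_substitution_is_union_of_singles(planted_c4):
    asm, _ = planted_c4

    def keys(recs):
        return {(r.atom_a.key(), r.atom_b.key(), r.contact_type) for r in recs}

    single_a = keys(mutate_in_silico_contact_check(asm, [("A", 7, "LEU")]))
    single_b = keys(mutate_in_silico_contact_check(asm, [("B", 27, "LYS")]))
    double = keys(
        mutate_in_silico_contact_check(asm, [("A", 7, "LEU"), ("B", 27, "LYS")])
    )
    assert double == single_a | single_b


def test_unknown_residue_name_errors(planted_c4):
    asm, _ = planted_c4
    with pytest.raises(ValueError):
        mutate_in_silico_contact_check(asm, [("A", 7, "XXX")])
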