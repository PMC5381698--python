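"""Typed atomic contacts and lock / interlock classification.

Contact criteria are heavy-atom and distance-only: the target structures carry
no hydrogens and at ~3.3 Å resolution angular hydrogen-bond criteria are not
reliable.  Donor/acceptor capability comes from a fixed per-residue atom table
rather than computed chemistry.

* hydrogen bond — donor-capable N/O to acceptor-capable N/O at <= 3.5 Å
* salt bridge  — side-chain N of Arg/Lys/His to side-chain O of Asp/Glu at <= 4.0 Å
* hydrophobic  — side-chain carbon pairs of apolar residues at <= 4.5 Å

A *binding region* (e.g. the sugar-binding loop of a nucleotidyltransferase)
is classified by where its stabilizing contacts come from: an intramolecular
**lock** (same chain, far in sequence) or an intermolecular **interlock**
(neighbouring subunit), the quaternary mechanism by which oligomeric
nucleotidyltransferases such as octameric human UDP-glucose pyrophosphorylase
brace the sugar-binding region (Arg of the loop to an Asp at the base of the
neighbour's C-terminal domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Assembly, RegionDefinition

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "InterlockReport",
    "detect_contacts",
    "detect_interlock",
    "mutate_in_silico_contact_check",
    "RESIDUE_HEAVY_ATOMS",
    "DONOR_ATOMS",
    "ACCEPTOR_ATOMS",
]


@dataclass(frozen=True)
class ContactCriteria:
    hbond_cutoff: float = 3.5  # Å
    salt_bridge_cutoff: float = 4.0  # Å
    hydrophobic_cutoff: float = 4.5  # Å


# Fixed donor/acceptor capability table (side chains; backbone handled below).
DONOR_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}
ACCEPTOR_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}
_SALT_BASIC_N: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}
_SALT_ACIDIC_O: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}
_APOLAR_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"})

#: Standard heavy-atom composition per residue type (backbone + side chain),
#: used by the in-silico substitution check to decide which atoms a
#: replacement residue retains.
RESIDUE_HEAVY_ATOMS: dict[str, frozenset[str]] = {
    name: frozenset({"N", "CA", "C", "O"} | set(side))
    for name, side in {
        "GLY": [],
        "ALA": ["CB"],
        "SER": ["CB", "OG"],
        "CYS": ["CB", "SG"],
        "VAL": ["CB", "CG1", "CG2"],
        "THR": ["CB", "OG1", "CG2"],
        "ILE": ["CB", "CG1", "CG2", "CD1"],
        "LEU": ["CB", "CG", "CD1", "CD2"],
        "PRO": ["CB", "CG", "CD"],
        "MET": ["CB", "CG", "SD", "CE"],
        "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
        "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        "ASP": ["CB", "CG", "OD1", "OD2"],
        "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
        "ASN": ["CB", "CG", "OD1", "ND2"],
        "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
        "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
        "LYS": ["CB", "CG", "CD", "CE", "NZ"],
        "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    }.items()
}


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    seq_num: int
    res_name: str
    atom_name: str

    def key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.atom_name)


@dataclass(frozen=True)
class ContactRecord:
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float  # Å
    contact_type: str  # {hbond, salt_bridge, hydrophobic}
    scope: str  # {intra_chain, inter_chain}

    def involves(self, chain_id: str, seq_num: int) -> bool:
        return (self.atom_a.chain_id, self.atom_a.seq_num) == (chain_id, seq_num) or (
            self.atom_b.chain_id,
            self.atom_b.seq_num,
        ) == (chain_id, seq_num)


def _is_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N":  # backbone amide
        return True
    return atom_name in DONOR_ATOMS.get(res_name, frozenset())


def _is_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):  # backbone carbonyl / terminal carboxylate
        return True
    return atom_name in ACCEPTOR_ATOMS.get(res_name, frozenset())


def _classify_pair(
    a: AtomRef, b: AtomRef, dist: float, criteria: ContactCriteria
) -> list[str]:
    types = []
    if dist <= criteria.hbond_cutoff:
        no = {"N", "O"}
        if (
            a.atom_name[:1] in no
            and b.atom_name[:1] in no
            and (
                (_is_donor(a.res_name, a.atom_name) and _is_acceptor(b.res_name, b.atom_name))
                or (_is_donor(b.res_name, b.atom_name) and _is_acceptor(a.res_name, a.atom_name))
            )
        ):
            types.append("hbond")
    if dist <= criteria.salt_bridge_cutoff:
        for basic, acidic in ((a, b), (b, a)):
            if basic.atom_name in _SALT_BASIC_N.get(
                basic.res_name, frozenset()
            ) and acidic.atom_name in _SALT_ACIDIC_O.get(acidic.res_name, frozenset()):
                types.append("salt_bridge")
                break
    if dist <= criteria.hydrophobic_cutoff:
        if (
            a.res_name in _APOLAR_RESIDUES
            and b.res_name in _APOLAR_RESIDUES
            and a.atom_name.startswith("C")
            and b.atom_name.startswith("C")
            and a.atom_name not in ("C", "CA")
            and b.atom_name not in ("C", "CA")
        ):
            types.append("hydrophobic")
    return types


def _atom_table(assembly: Assembly) -> tuple[list[AtomRef], np.ndarray]:
    refs: list[AtomRef] = []
    coords: list[np.ndarray] = []
    for chain in assembly.chains:
        for res in chain.protein_residues():
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                refs.append(AtomRef(chain.chain_id, res.seq_num, res.res_name, atom.name))
                coords.append(atom.coords)
    return refs, (np.array(coords) if coords else np.empty((0, 3)))


def _order_pair(a: AtomRef, b: AtomRef) -> tuple[AtomRef, AtomRef]:
    ka = (a.chain_id, a.seq_num, a.atom_name)
    kb = (b.chain_id, b.seq_num, b.atom_name)
    return (a, b) if ka <= kb else (b, a)


def detect_contacts(
    assembly: Assembly, criteria: ContactCriteria | None = None
) -> list[ContactRecord]:
    """All typed heavy-atom contacts in the assembly.

    Neighbour candidates come from a k-d tree at the largest cutoff; each
    candidate pair is then typed against the criteria table.  Atoms of the
    same residue never form a contact; each unordered pair is emitted once
    (ordered by chain, residue number, atom name), possibly with several
    records when it satisfies several contact types.
    """
    criteria = criteria or ContactCriteria()
    refs, coords = _atom_table(assembly)
    if len(refs) < 2:
        return []
    max_cut = max(
        criteria.hbond_cutoff, criteria.salt_bridge_cutoff, criteria.hydrophobic_cutoff
    )
    tree = cKDTree(coords)
    records: list[ContactRecord] = []
    for i, j in tree.query_pairs(max_cut):
        a, b = refs[i], refs[j]
        if (a.chain_id, a.seq_num) == (b.chain_id, b.seq_num):
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if dist <= 0.0:
            continue
        for ctype in _classify_pair(a, b, dist, criteria):
            first, second = _order_pair(a, b)
            records.append(
                ContactRecord(
                    atom_a=first,
                    atom_b=second,
                    distance=dist,
                    contact_type=ctype,
                    scope="intra_chain" if a.chain_id == b.chain_id else "inter_chain",
                )
            )
    records.sort(
        key=lambda r: (
            r.atom_a.chain_id,
            r.atom_a.seq_num,
            r.atom_a.atom_name,
            r.atom_b.chain_id,
            r.atom_b.seq_num,
            r.atom_b.atom_name,
            r.contact_type,
        )
    )
    return records


DEFAULT_MIN_SEQ_SEPARATION = 20  # residues; tertiary vs local backbone contact


@dataclass
class InterlockReport:
    binding_region: RegionDefinition
    stabilizing_contacts: list[ContactRecord]
    classification: str  # {lock, interlock, both, none}
    partner_pairs: list[tuple[tuple[str, int], tuple[str, int]]]  # (region res, partner res)
    recurring_pairs: list[tuple[int, int]] = field(default_factory=list)
    # (region seq_num, partner seq_num) seen in every chain, symmetry check
    asymmetric_chains: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def detect_interlock(
    assembly: Assembly,
    binding_region: RegionDefinition,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION,
    criteria: ContactCriteria | None = None,
    offsets: dict[str, int] | None = None,
    contacts: list[ContactRecord] | None = None,
) -> InterlockReport:
    """Classify how a binding region is stabilized: lock vs interlock.

    Contacts touching the region with at least one atom are collected; an
    **interlock** needs at least one inter-chain stabilizing contact, a
    **lock** at least one intra-chain contact separated by
    ``min_seq_separation`` or more in sequence (local backbone contacts do not
    count as tertiary stabilization).  ``both`` and ``none`` are allowed.  In
    a symmetric oligomer the same (region residue, partner residue) pairs
    should recur in every chain; chains missing a recurring pair are listed.
    """
    offsets = offsets or {}
    chain_ids = [c.chain_id for c in assembly.protein_chains()]
    resolved_any = False
    for cid in chain_ids:
        chain = assembly.chain(cid)
        off = offsets.get(cid, 0)
        if any(res.seq_num + off in binding_region for res in chain.protein_residues()):
            resolved_any = True
            break
    if not resolved_any:
        raise ValueError(
            f"binding region {binding_region.name!r} resolves in no chain of {assembly.id}"
        )

    if contacts is None:
        contacts = detect_contacts(assembly, criteria)

    def in_region(ref: AtomRef) -> bool:
        return ref.seq_num + offsets.get(ref.chain_id, 0) in binding_region

    stabilizing: list[ContactRecord] = []
    partner_pairs: list[tuple[tuple[str, int], tuple[str, int]]] = []
    has_inter = False
    has_lock = False
    for rec in contacts:
        a_in, b_in = in_region(rec.atom_a), in_region(rec.atom_b)
        if not (a_in or b_in):
            continue
        stabilizing.append(rec)
        region_ref, partner_ref = (
            (rec.atom_a, rec.atom_b) if a_in else (rec.atom_b, rec.atom_a)
        )
        if b_in and a_in:
            continue  # both ends inside the region: internal, not stabilizing partner
        pair = (
            (region_ref.chain_id, region_ref.seq_num),
            (partner_ref.chain_id, partner_ref.seq_num),
        )
        if pair not in partner_pairs:
            partner_pairs.append(pair)
        if rec.scope == "inter_chain":
            has_inter = True
        elif abs(rec.atom_a.seq_num - rec.atom_b.seq_num) >= min_seq_separation:
            has_lock = True

    if has_inter and has_lock:
        classification = "both"
    elif has_inter:
        classification = "interlock"
    elif has_lock:
        classification = "lock"
    else:
        classification = "none"

    # symmetry check: normalized (region seq, partner seq) pairs per chain
    per_chain: dict[str, set[tuple[int, int]]] = {cid: set() for cid in chain_ids}
    for (rchain, rseq), (pchain, pseq) in partner_pairs:
        per_chain.setdefault(rchain, set()).add(
            (rseq + offsets.get(rchain, 0), pseq + offsets.get(pchain, 0))
        )
    # a pair "recurs" when a majority of chains shows it; chains lacking a
    # recurring pair deviate from the oligomer's symmetry
    counts: dict[tuple[int, int], int] = {}
    for pairs in per_chain.values():
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
    n_chains = len(per_chain)
    recurring = {p for p, c in counts.items() if c > n_chains / 2}
    asymmetric = [
        cid for cid, pairs in per_chain.items() if recurring and not recurring <= pairs
    ]
    warns = []
    if asymmetric:
        warns.append(
            f"recurring partner pairs {sorted(recurring)} absent in chains {asymmetric}"
        )
    return InterlockReport(
        binding_region=binding_region,
        stabilizing_contacts=stabilizing,
        classification=classification,
        partner_pairs=partner_pairs,
        recurring_pairs=sorted(recurring),
        asymmetric_chains=asymmetric,
        warnings=warns,
    )


def mutate_in_silico_contact_check(
    assembly: Assembly,
    substitutions: list[tuple[str, int, str]],
    criteria: ContactCriteria | None = None,
    contacts: list[ContactRecord] | None = None,
) -> list[ContactRecord]:
    """Contacts abolished by truncating substituted side chains.

    A purely geometric plausibility screen for point mutations (e.g. the
    charge-reversal and truncation mutants probing an interlock pair): each
    substituted residue keeps only the heavy atoms shared with the replacement
    residue type — no rotamer building — and every detected contact that
    involves a removed atom is reported as abolished.  The delta of a multiple
    substitution is the union of the single-substitution deltas.
    """
    removed: set[tuple[str, int, str]] = set()
    for chain_id, seq_num, new_name in substitutions:
        new_name = new_name.upper()
        if new_name not in RESIDUE_HEAVY_ATOMS:
            raise ValueError(f"unknown residue name {new_name!r}")
        chain = assembly.chain(chain_id)
        res = chain.residue(seq_num)
        if res is None:
            raise ValueError(f"no residue {seq_num} in chain {chain_id}")
        keep = RESIDUE_HEAVY_ATOMS[new_name]
        for atom in res.atoms:
            if atom.element == "H" or atom.name in keep:
                continue
            removed.add((chain_id, seq_num, atom.name))
    if not removed:
        return []
    if contacts is None:
        contacts = detect_contacts(assembly, criteria)
    return [
        rec
        for rec in contacts
        if rec.atom_a.key() in removed or rec.atom_b.key() in removed
    ]
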