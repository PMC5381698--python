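"""Ground-truth fixture generators for every analysis stage.

Toy subunits are geometric, not physical: poly-alanine-like chains whose
N/CA/C/O/CB atoms sit at ideal bond lengths on an idealized helical path.
There is no force field and no residue chemistry beyond atom naming — just
enough for the contact-type tables (an Arg/Asp pair can be planted with real
guanidinium/carboxylate atom names).  Because the generators know their own
ground truth (planted point group, contact distances, hinge deformation,
kinetic parameters), every analysis module can be tested closed-loop with no
external structures, and fixtures are written as standard PDB files so the
parsing layer is exercised end to end.

All randomness flows from explicit integer seeds; the same seed and
parameters always produce bit-identical output.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Assembly, Atom, Chain, Residue
from .structure_io import RegionDefinition
from .assembly_symmetry import SymmetryModel
from .biophys_models import KineticsDataset, _hill_model, _mm_model
from .superpose import RigidTransform

__all__ = [
    "make_subunit",
    "make_assembly",
    "plant_contact",
    "make_apo_holo_pair",
    "scale_assembly",
    "simulate_kinetics",
    "simulate_melt",
    "copy_assembly",
    "set_residue_type",
    "AssemblyGroundTruth",
    "DeformationGroundTruth",
]

# helix construction parameters: consecutive Cα ~3.8 Å apart
_HELIX_RADIUS = 2.3  # Å
_HELIX_TURN = 100.0  # degrees per residue
_HELIX_RISE = 1.42  # Å per residue

# pseudo side-chain extension geometry: atoms stacked outward from CB
_SIDECHAIN_STEP = 1.5  # Å between successive pseudo side-chain atoms
_SIDECHAIN_EXTENSIONS: dict[str, list[str]] = {
    # beyond CB, in outward order; branch atoms get a perpendicular offset
    "ALA": [],
    "ARG": ["CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASP": ["CG", "OD1", "OD2"],
    "GLU": ["CG", "CD", "OE1", "OE2"],
    "LYS": ["CG", "CD", "CE", "NZ"],
    "LEU": ["CG", "CD1", "CD2"],
    "SER": ["OG"],
    "GLY": [],
}
_BRANCH_ATOMS = frozenset({"NH1", "NH2", "OD1", "OD2", "OE1", "OE2", "CD1", "CD2"})


def copy_assembly(assembly: Assembly) -> Assembly:
    return copy.deepcopy(assembly)


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def make_subunit(seed: int, n_residues: int, noise_sd: float = 0.0) -> Chain:
    """A poly-alanine toy chain (N, CA, C, O, CB) on an idealized helix.

    Residues are numbered from 1.  ``noise_sd`` adds seeded Gaussian jitter to
    every coordinate (0 by default: ideal geometry, bit-identical per seed).
    """
    if n_residues < 10:
        raise ValueError(f"need at least 10 residues, got {n_residues}")
    rng = np.random.default_rng(seed)
    # Cα path
    ca = np.empty((n_residues, 3))
    for i in range(n_residues):
        ang = math.radians(_HELIX_TURN * i)
        ca[i] = (
            _HELIX_RADIUS * math.cos(ang),
            _HELIX_RADIUS * math.sin(ang),
            _HELIX_RISE * i,
        )
    residues: list[Residue] = []
    serial = 0
    for i in range(n_residues):
        # local frame: tangent along the chain, radial direction outward
        lo, hi = max(i - 1, 0), min(i + 1, n_residues - 1)
        t = ca[hi] - ca[lo]
        t /= np.linalg.norm(t)
        radial = np.array([ca[i][0], ca[i][1], 0.0])
        radial = radial - np.dot(radial, t) * t
        u = radial / np.linalg.norm(radial)
        v = np.cross(t, u)

        n_pos = ca[i] - 1.46 * (0.5 * t + math.sqrt(1 - 0.25) * v)
        c_pos = ca[i] + 1.52 * (0.5 * t - math.sqrt(1 - 0.25) * v)
        o_pos = c_pos + 1.23 * v
        cb_pos = ca[i] + 1.53 * u
        atoms = []
        for name, pos in (("N", n_pos), ("CA", ca[i]), ("C", c_pos), ("O", o_pos), ("CB", cb_pos)):
            serial += 1
            jitter = rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else 0.0
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=_element_of(name),
                    coords=np.asarray(pos, dtype=float) + jitter,
                )
            )
        residues.append(
            Residue(chain_id="A", seq_num=i + 1, res_name="ALA", atoms=atoms)
        )
    return Chain(chain_id="A", residues=residues)


def set_residue_type(residue: Residue, res_name: str) -> None:
    """Rename a toy residue and extend a pseudo side chain beyond CB.

    Extension atoms march outward from CB along the CA→CB direction at
    1.5 Å steps; branch atoms (carboxylate oxygens, guanidinium nitrogens)
    receive a perpendicular offset so branch pairs are not coincident.
    Enough realism for the contact-type and truncation tables, nothing more.
    """
    if res_name not in _SIDECHAIN_EXTENSIONS:
        raise ValueError(f"unsupported toy residue type {res_name!r}")
    ca = residue.atom("CA")
    cb = residue.atom("CB")
    if ca is None or cb is None:
        raise ValueError("residue lacks CA/CB")
    out = cb.coords - ca.coords
    out = out / np.linalg.norm(out)
    # branch perpendicular from local backbone geometry (N -> C), so the
    # construction commutes with any rigid placement of the chain
    n_at, c_at = residue.atom("N"), residue.atom("C")
    if n_at is not None and c_at is not None:
        tangent = c_at.coords - n_at.coords
    else:
        tangent = np.array([0.0, 0.0, 1.0])
    perp = np.cross(out, tangent)
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(out, [1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)

    residue.res_name = res_name
    base = cb.coords
    serial = max(a.serial for a in residue.atoms)
    step = 0
    sign = 1.0
    for name in _SIDECHAIN_EXTENSIONS[res_name]:
        step += 1
        pos = base + step * _SIDECHAIN_STEP * out
        if name in _BRANCH_ATOMS:
            pos = pos + sign * 0.8 * perp - 0.5 * _SIDECHAIN_STEP * out
            sign = -sign
            step -= 1  # branches share the same shell
        serial += 1
        residue.atoms.append(
            Atom(serial=serial, name=name, element=_element_of(name), coords=pos)
        )


@dataclass
class AssemblyGroundTruth:
    point_group: str
    order: int
    principal_axis: np.ndarray
    secondary_axes: list[np.ndarray]
    rings: list[list[str]]  # chain ids per Cn ring, in rotation order
    generators: dict[str, RigidTransform] = field(default_factory=dict)
    # chain id -> transform placing the template subunit at that chain

    def ring_successor(self) -> dict[str, str]:
        """Chain -> ring neighbour map that is invariant under the full group.

        In a dihedral assembly the perpendicular two-fold conjugates the
        principal rotation to its inverse, so the "next neighbour" direction
        seen from a flipped ring is reversed; pairing every chain with its
        successor *in its own frame* (second ring traversed backwards) keeps
        the planted-contact pattern Dn-symmetric.
        """
        succ = {}
        for idx, ring in enumerate(self.rings):
            ordered = ring if (idx == 0 or not self.point_group.startswith("D")) else ring[::-1]
            for i, cid in enumerate(ordered):
                succ[cid] = ordered[(i + 1) % len(ordered)]
        return succ

    def to_model(self) -> SymmetryModel:
        cycles = self.rings if self.point_group.startswith(("C", "D")) else []
        return SymmetryModel(
            point_group=self.point_group,
            order=self.order,
            principal_axis=self.principal_axis,
            secondary_axes=self.secondary_axes,
            chain_cycle=cycles,
            fit_residual=0.0,
            heterologous=len(self.rings) == 1,
        )


def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


def _rot_x_180() -> np.ndarray:
    return np.diag([1.0, -1.0, -1.0])


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWX"


def make_assembly(
    subunit: Chain,
    point_group: str,
    n: int,
    radius: float | None = None,
    assembly_id: str = "synthetic",
    clash_cutoff: float = 2.5,
) -> tuple[Assembly, AssemblyGroundTruth]:
    """Arrange copies of a subunit with exact Cn or Dn symmetry about z.

    Cn: n copies rotated by 360/n about z, the subunit first pushed out
    radially so neighbouring chains do not clash.  Dn: a second ring, related
    to the first by a two-fold about x, stacked below.  Chain ids run A, B, …
    ring by ring in rotation order.  The exact planted symmetry is returned
    alongside as ground truth.
    """
    if point_group not in ("C", "D", "Cn", "Dn"):
        raise ValueError("point_group must be 'Cn' or 'Dn'")
    dihedral = point_group.startswith("D")
    if n < 2:
        raise ValueError("n must be >= 2")

    coords = np.array([a.coords for r in subunit.residues for a in r.atoms])
    centroid = coords.mean(axis=0)
    size = float(np.max(np.linalg.norm(coords - centroid, axis=1)))
    if radius is None:
        # chord between neighbouring centroids = 2 R sin(pi/n) must exceed
        # twice the subunit radius plus clearance
        radius = (2.0 * size + 4.0) / (2.0 * math.sin(math.pi / n))

    # template: subunit centred at (radius, 0, +offset for D)
    z_shift = size + 2.0 if dihedral else 0.0
    template_shift = np.array([radius, 0.0, z_shift]) - centroid

    rings: list[list[str]] = []
    chains: list[Chain] = []
    generators: dict[str, RigidTransform] = {}
    next_id = 0

    def place(R: np.ndarray, ring: list[str]) -> None:
        nonlocal next_id
        cid = _CHAIN_IDS[next_id]
        next_id += 1
        transform = RigidTransform(R, R @ template_shift)
        new_res = []
        for res in subunit.residues:
            new_atoms = [
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    coords=transform.apply(a.coords),
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                )
                for a in res.atoms
            ]
            new_res.append(
                Residue(
                    chain_id=cid,
                    seq_num=res.seq_num,
                    res_name=res.res_name,
                    atoms=new_atoms,
                )
            )
        chains.append(Chain(chain_id=cid, residues=new_res))
        generators[cid] = transform
        ring.append(cid)

    ring1: list[str] = []
    for k in range(n):
        place(_rot_z(360.0 * k / n), ring1)
    rings.append(ring1)
    if dihedral:
        ring2: list[str] = []
        flip = _rot_x_180()
        for k in range(n):
            place(_rot_z(360.0 * k / n) @ flip, ring2)
        rings.append(ring2)

    assembly = Assembly(id=assembly_id, chains=chains)
    # clash check between all chain pairs
    from scipy.spatial import cKDTree

    arrays = [
        np.array([a.coords for r in c.residues for a in r.atoms]) for c in chains
    ]
    trees = [cKDTree(arr) for arr in arrays]
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            d = trees[i].query(arrays[j], k=1)[0].min()
            if d < clash_cutoff:
                raise ValueError(
                    f"chains {chains[i].chain_id}/{chains[j].chain_id} clash "
                    f"({d:.2f} Å < {clash_cutoff} Å): radial offset too small"
                )
    truth = AssemblyGroundTruth(
        point_group=f"D{n}" if dihedral else f"C{n}",
        order=n,
        principal_axis=np.array([0.0, 0.0, 1.0]),
        secondary_axes=[np.array([1.0, 0.0, 0.0])] if dihedral else [],
        rings=rings,
        generators=generators,
    )
    return assembly, truth


def plant_contact(
    assembly: Assembly,
    region_seq: int,
    partner_seq: int,
    distance: float,
    chain_map: dict[str, str] | None = None,
    truth: AssemblyGroundTruth | None = None,
    region_res: str = "ARG",
    partner_res: str = "ASP",
    region_atom: str = "NH1",
    partner_atom: str = "OD1",
    segment_halfwidth: int = 2,
) -> Assembly:
    """Plant a side-chain contact at an exact target distance.

    Residue ``region_seq`` of every chain becomes an Arg-like residue and
    ``partner_seq`` an Asp-like one; the partner chain's local segment
    (``partner_seq`` ± ``segment_halfwidth``) is then translated minimally so
    the designated side-chain atoms sit exactly ``distance`` Å apart.
    ``chain_map`` says whose region pairs with whose partner (region chain →
    partner chain); by default each chain pairs with its ring successor from
    ``truth`` (an intra-chain lock when the map sends a chain to itself).
    Because all chains are congruent, the same local edit recurs in every
    copy and the planted point group is preserved exactly.
    """
    if distance < 2.5:
        raise ValueError("target distance below 2.5 Å would imply a clash")
    assembly = copy_assembly(assembly)
    if chain_map is None:
        if truth is not None:
            chain_map = truth.ring_successor()
        elif len(assembly.chains) == 1:
            cid = assembly.chains[0].chain_id
            chain_map = {cid: cid}
        else:
            ids = assembly.chain_ids()
            chain_map = {a: b for a, b in zip(ids, ids[1:] + ids[:1])}

    for chain in assembly.chains:
        reg = chain.residue(region_seq)
        par = chain.residue(partner_seq)
        if reg is None or par is None:
            raise ValueError(
                f"chain {chain.chain_id} lacks residue {region_seq} or {partner_seq}"
            )
        set_residue_type(reg, region_res)
        set_residue_type(par, partner_res)

    for region_chain, partner_chain in chain_map.items():
        reg_atom = assembly.chain(region_chain).residue(region_seq).atom(region_atom)
        par_res = assembly.chain(partner_chain).residue(partner_seq)
        par_atom = par_res.atom(partner_atom)
        if reg_atom is None or par_atom is None:
            raise ValueError("designated side-chain atoms missing after typing")
        gap = reg_atom.coords - par_atom.coords
        d = float(np.linalg.norm(gap))
        shift = (1.0 - distance / d) * gap
        chain_obj = assembly.chain(partner_chain)
        for res in chain_obj.residues:
            if abs(res.seq_num - partner_seq) <= segment_halfwidth:
                for atom in res.atoms:
                    atom.coords = atom.coords + shift
    return assembly


@dataclass
class DeformationGroundTruth:
    region: RegionDefinition
    angle: float  # degrees
    hinge_point: np.ndarray  # on the template chain
    hinge_axis: np.ndarray  # unit vector
    expected_ca: dict[int, float]  # seq_num -> chord displacement, template chain
    expected_max_ca: float
    expected_max_sidechain: float
    compaction_factor: float | None = None

    @property
    def expected_percent_volume_change(self) -> float | None:
        if self.compaction_factor is None:
            return None
        return (self.compaction_factor**3 - 1.0) * 100.0


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def make_apo_holo_pair(
    assembly: Assembly,
    region: RegionDefinition,
    hinge_point: np.ndarray,
    hinge_axis: np.ndarray,
    angle: float,
    compaction_factor: float | None = None,
    template_chain: str | None = None,
) -> tuple[Assembly, Assembly, DeformationGroundTruth]:
    """An (apo, holo) pair with a known rigid region deformation.

    The holo state rotates every region residue by ``angle`` about the hinge
    (given on the template chain; mapped onto the other chains through each
    chain's placement so symmetric assemblies deform symmetrically), then
    optionally shrinks the whole assembly isotropically about its centroid by
    ``compaction_factor``.  Expected Cα displacements follow the chord
    formula 2·d·sin(angle/2) with d the Cα's distance to the hinge axis,
    computed analytically from the construction before any compaction.
    """
    if not 0.0 <= angle <= 30.0:
        raise ValueError("hinge angle must be within [0, 30] degrees")
    hinge_point = np.asarray(hinge_point, dtype=float)
    hinge_axis = np.asarray(hinge_axis, dtype=float)
    hinge_axis = hinge_axis / np.linalg.norm(hinge_axis)

    apo = copy_assembly(assembly)
    holo = copy_assembly(assembly)
    template_chain = template_chain or apo.chains[0].chain_id

    # map the hinge onto each chain by superposing the template onto it
    from .superpose import kabsch_fit

    tpl_ca = apo.chain(template_chain).ca_coords()
    R = _rotation_about_axis(hinge_axis, angle)

    expected: dict[int, float] = {}
    expected_sc: dict[int, float] = {}
    for chain in holo.chains:
        ca = {n: c for n, c in ((r.seq_num, r.ca.coords) for r in chain.protein_residues() if r.ca)}
        shared = sorted(set(tpl_ca) & set(ca))
        tpl_pts = np.array([tpl_ca[n] for n in shared])
        ch_pts = np.array([ca[n] for n in shared])
        fit = kabsch_fit(ch_pts, tpl_pts)  # template -> this chain
        point_c = fit.transform.apply(hinge_point)
        axis_c = fit.transform.rotation @ hinge_axis
        R_c = _rotation_about_axis(axis_c, angle)
        for res in chain.residues:
            if res.seq_num not in region:
                continue
            for atom in res.atoms:
                rel = atom.coords - point_c
                moved = R_c @ rel + point_c
                if chain.chain_id == template_chain:
                    disp = 2.0 * _dist_to_axis(rel, axis_c) * math.sin(
                        math.radians(angle) / 2.0
                    )
                    if atom.name == "CA":
                        expected[res.seq_num] = disp
                    elif not atom.is_backbone:
                        expected_sc[res.seq_num] = max(
                            expected_sc.get(res.seq_num, 0.0), disp
                        )
                atom.coords = moved

    if compaction_factor is not None:
        holo = scale_assembly(holo, compaction_factor)

    truth = DeformationGroundTruth(
        region=region,
        angle=angle,
        hinge_point=hinge_point,
        hinge_axis=hinge_axis,
        expected_ca=expected,
        expected_max_ca=max(expected.values(), default=0.0),
        expected_max_sidechain=max(expected_sc.values(), default=0.0),
        compaction_factor=compaction_factor,
    )
    return apo, holo, truth


def _dist_to_axis(rel: np.ndarray, axis: np.ndarray) -> float:
    return float(np.linalg.norm(rel - np.dot(rel, axis) * axis))


def scale_assembly(assembly: Assembly, factor: float) -> Assembly:
    """Isotropic scaling about the assembly centroid (compaction for < 1)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = copy_assembly(assembly)
    coords = out.heavy_coords(protein_only=False)
    centroid = coords.mean(axis=0)
    for _, _, atom in out.all_atoms():
        atom.coords = centroid + factor * (atom.coords - centroid)
    return out


# ---------------------------------------------------------------------------
# Kinetics / melt simulators


def simulate_kinetics(
    model: str,
    params: dict[str, float],
    conc: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticsDataset:
    """Velocity data from a known MM or Hill model with Gaussian noise.

    ``params`` holds ``v_max``, ``k`` and (Hill) ``h``; ``noise_sd`` is the
    additive Gaussian σ in velocity units.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.asarray(conc, dtype=float)
    if model == "MM":
        y = _mm_model(x, params["v_max"], params["k"])
    elif model == "Hill":
        y = _hill_model(x, params["v_max"], params["k"], params["h"])
    else:
        raise ValueError(f"unknown model {model!r}")
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, x.shape)
    return KineticsDataset(substrate_conc=x, velocity=y)


def simulate_melt(
    t_m: float,
    slope: float,
    temperatures: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 0.0,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A Boltzmann-sigmoid melt curve with Gaussian noise.

    Returns (temperatures, fluorescence); the noiseless signal is
    baseline + amplitude / (1 + exp((t_m − T)/slope)).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    T = np.asarray(temperatures, dtype=float)
    F = baseline + amplitude / (1.0 + np.exp((t_m - T) / slope))
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, T.shape)
    return T, F
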