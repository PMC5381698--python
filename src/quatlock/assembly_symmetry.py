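"""Point-group detection and interface typing for homo-oligomeric assemblies.

A cyclic group Cn is called when a single rigid rotation by 360/n about a
common axis maps every chain onto another chain of the assembly (within a
residual tolerance) and the induced chain permutation decomposes into cycles
of length n.  A dihedral group Dn additionally requires a two-fold axis
perpendicular to the principal axis that exchanges the two Cn rings — the
arrangement of octameric UDP-glucose pyrophosphorylase, where two cyclic C4
tetramers stack with D4 symmetry.

Candidate operations come from pairwise chain superpositions (Cα atoms matched
by residue number); an operation is accepted only if, applied globally, it
maps *every* chain onto some chain.  If the full assembly supports nothing
better than C1 but a subset of chains is internally symmetric, the model is
downgraded: the full-assembly label stays C1 while the best consistent subset
and its group are reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Assembly, Chain, RegionDefinition
from .superpose import RigidTransform, kabsch_fit

__all__ = [
    "SymmetryModel",
    "InterfaceLabel",
    "chain_pair_transform",
    "detect_point_group",
    "classify_interfaces",
    "DEFAULT_ANGLE_TOL",
    "DEFAULT_RESIDUAL_TOL",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_MIN_CONTACT_PAIRS",
]

DEFAULT_ANGLE_TOL = 5.0  # degrees
DEFAULT_RESIDUAL_TOL = 1.5  # Å, mean Cα RMSD of symmetry-mapped chains
DEFAULT_CONTACT_CUTOFF = 4.5  # Å heavy-atom, interface detection
DEFAULT_MIN_CONTACT_PAIRS = 30  # atom pairs below cutoff to call an interface


@dataclass
class SymmetryModel:
    """Detected point group of an assembly.

    ``chain_cycle`` lists the cycles of the generating rotation's chain
    permutation (e.g. ``[["A", "B", "C", "D"]]`` for a C4 tetramer).
    ``heterologous`` is True when that permutation is a single n-cycle —
    the "face-to-back" arrangement in which every subunit uses two different
    surfaces to touch its ring neighbours.
    """

    point_group: str
    order: int  # rotational order n of the principal axis (1 for C1)
    principal_axis: np.ndarray
    secondary_axes: list[np.ndarray] = field(default_factory=list)
    chain_cycle: list[list[str]] = field(default_factory=list)
    fit_residual: float = 0.0
    heterologous: bool = False
    subset_group: str | None = None  # best group over a consistent chain subset
    subset_chains: list[str] | None = None
    outlier_chains: list[str] = field(default_factory=list)


@dataclass
class InterfaceLabel:
    chain_pair: tuple[str, str]
    label: str  # {end_to_end, side_by_side, none}
    contact_area_proxy: int  # inter-chain heavy-atom pairs below cutoff
    terminal_fraction: float = 0.0  # fraction of contact pairs in the terminal regions
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Chain correspondence helpers


def _shared_ca(chain_a: Chain, chain_b: Chain) -> tuple[np.ndarray, np.ndarray]:
    ca_a = chain_a.ca_coords()
    ca_b = chain_b.ca_coords()
    shared = sorted(set(ca_a) & set(ca_b))
    A = np.array([ca_a[n] for n in shared]) if shared else np.empty((0, 3))
    B = np.array([ca_b[n] for n in shared]) if shared else np.empty((0, 3))
    return A, B


def chain_pair_transform(
    assembly: Assembly, chain_a: str, chain_b: str
) -> tuple[RigidTransform, float, np.ndarray, float]:
    """Superpose chain ``chain_a`` onto ``chain_b``.

    Returns ``(transform, angle_deg, axis, rmsd)`` where the transform maps
    a's coordinates onto b's, correspondence by residue number.  The angle is
    in [0, 180] degrees and the axis a unit vector (sign fixed toward +z).
    """
    a = assembly.chain(chain_a)
    b = assembly.chain(chain_b)
    A, B = _shared_ca(a, b)
    if len(A) < 3:
        raise ValueError(
            f"chains {chain_a}/{chain_b} share only {len(A)} numbered Cα atoms"
        )
    fit = kabsch_fit(B, A)  # transform moving a onto reference b
    angle, axis = fit.transform.angle_axis()
    return fit.transform, angle, axis, fit.rmsd


# ---------------------------------------------------------------------------
# Point-group detection


def _apply_op_residual(
    op: RigidTransform, coords: dict[str, np.ndarray], chain_ids: list[str]
) -> tuple[dict[str, str], float] | None:
    """Chain permutation induced by ``op``, or None if some chain maps nowhere.

    ``coords`` holds, per chain, an (N, 3) Cα array over the common residue
    set, so RMSD between transformed chain i and candidate chain j is a plain
    row-wise comparison.
    """
    mapping: dict[str, str] = {}
    residuals: list[float] = []
    for cid in chain_ids:
        moved = op.apply(coords[cid])
        best, best_rmsd = None, np.inf
        for other in chain_ids:
            d = moved - coords[other]
            rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
            if rmsd < best_rmsd:
                best, best_rmsd = other, rmsd
        mapping[cid] = best
        residuals.append(best_rmsd)
    if len(set(mapping.values())) != len(chain_ids):
        return None
    return mapping, float(np.mean(residuals))


def _common_ca_coords(assembly: Assembly, chain_ids: list[str]) -> dict[str, np.ndarray] | None:
    per_chain = {cid: assembly.chain(cid).ca_coords() for cid in chain_ids}
    shared: set[int] | None = None
    for ca in per_chain.values():
        shared = set(ca) if shared is None else shared & set(ca)
    if not shared or len(shared) < 3:
        return None
    order = sorted(shared)
    return {cid: np.array([per_chain[cid][n] for n in order]) for cid in chain_ids}


def _cycles(mapping: dict[str, str]) -> list[list[str]]:
    seen: set[str] = set()
    cycles = []
    for start in mapping:
        if start in seen:
            continue
        cyc = [start]
        seen.add(start)
        nxt = mapping[start]
        while nxt != start:
            cyc.append(nxt)
            seen.add(nxt)
            nxt = mapping[nxt]
        cycles.append(cyc)
    return cycles


def _candidate_ops(
    coords: dict[str, np.ndarray], chain_ids: list[str], residual_tol: float
) -> list[tuple[RigidTransform, float, np.ndarray, float]]:
    """Pairwise chain-onto-chain transforms usable as symmetry operations."""
    ops = []
    for a, b in itertools.permutations(chain_ids, 2):
        fit = kabsch_fit(coords[b], coords[a])
        if fit.rmsd > residual_tol:
            continue
        angle, axis = fit.transform.angle_axis()
        ops.append((fit.transform, angle, axis, fit.rmsd))
    return ops


def _find_cn(
    coords: dict[str, np.ndarray],
    chain_ids: list[str],
    n: int,
    angle_tol: float,
    residual_tol: float,
) -> tuple[RigidTransform, dict[str, str], float, np.ndarray] | None:
    """A generator rotation realizing Cn over these chains, if any."""
    target = 360.0 / n
    for op, angle, axis, _ in _candidate_ops(coords, chain_ids, residual_tol):
        if abs(angle - target) > angle_tol:
            continue
        res = _apply_op_residual(op, coords, chain_ids)
        if res is None:
            continue
        mapping, residual = res
        if residual > residual_tol:
            continue
        if any(len(c) != n for c in _cycles(mapping)):
            continue
        return op, mapping, residual, axis
    return None


def _perpendicular_twofold(
    coords: dict[str, np.ndarray],
    chain_ids: list[str],
    principal_axis: np.ndarray,
    angle_tol: float,
    residual_tol: float,
) -> list[tuple[RigidTransform, np.ndarray, float]]:
    found = []
    for op, angle, axis, _ in _candidate_ops(coords, chain_ids, residual_tol):
        if abs(angle - 180.0) > angle_tol:
            continue
        if abs(np.dot(axis, principal_axis)) > np.sin(np.radians(angle_tol)):
            continue
        res = _apply_op_residual(op, coords, chain_ids)
        if res is None or res[1] > residual_tol:
            continue
        found.append((op, axis, res[1]))
    return found


def _detect_on_subset(
    assembly: Assembly,
    chain_ids: list[str],
    angle_tol: float,
    residual_tol: float,
) -> SymmetryModel | None:
    """Best (highest-order) group on exactly these chains, or None for C1."""
    N = len(chain_ids)
    if N < 2:
        return None
    coords = _common_ca_coords(assembly, chain_ids)
    if coords is None:
        return None

    # Dn first (order 2n beats Cn of the same chain count), then Cn by
    # descending orbit size over divisors of N.
    if N % 2 == 0 and N >= 4:
        n = N // 2
        cn = _find_cn(coords, chain_ids, n, angle_tol, residual_tol)
        if cn is not None:
            op, mapping, residual, axis = cn
            twofolds = _perpendicular_twofold(
                coords, chain_ids, axis, angle_tol, residual_tol
            )
            if twofolds:
                cycles = _cycles(mapping)
                # distinct two-fold directions only (axes equal up to sign)
                sec: list[np.ndarray] = []
                for _, ax, _ in twofolds:
                    if all(
                        abs(float(np.dot(ax, prev))) < np.cos(np.radians(angle_tol))
                        for prev in sec
                    ):
                        sec.append(ax)
                mean_res = float(
                    np.mean([residual] + [r for _, _, r in twofolds])
                )
                return SymmetryModel(
                    point_group=f"D{n}",
                    order=n,
                    principal_axis=axis,
                    secondary_axes=sec,
                    chain_cycle=cycles,
                    fit_residual=mean_res,
                    heterologous=len(cycles) == 1,
                )
    divisors = [d for d in range(N, 1, -1) if N % d == 0]
    for n in divisors:
        cn = _find_cn(coords, chain_ids, n, angle_tol, residual_tol)
        if cn is not None:
            op, mapping, residual, axis = cn
            cycles = _cycles(mapping)
            return SymmetryModel(
                point_group=f"C{n}",
                order=n,
                principal_axis=axis,
                secondary_axes=[],
                chain_cycle=cycles,
                fit_residual=residual,
                heterologous=len(cycles) == 1,
            )
    return None


def detect_point_group(
    assembly: Assembly,
    angle_tol: float = DEFAULT_ANGLE_TOL,
    residual_tol: float = DEFAULT_RESIDUAL_TOL,
) -> SymmetryModel:
    """Detect the point group of a homo-oligomeric assembly.

    Returns the highest-order group whose operations map every chain onto
    another chain with mean Cα residual at most ``residual_tol`` and rotation
    angles within ``angle_tol`` of the ideal group angles.  Always returns a
    model; C1 when nothing better fits.  When the full assembly is C1 but a
    proper subset of chains is symmetric (e.g. one displaced subunit in an
    otherwise perfect ring), the subset group is reported in
    ``subset_group`` / ``subset_chains`` with the spoilers in
    ``outlier_chains``.
    """
    chain_ids = [c.chain_id for c in assembly.protein_chains()]
    if len(chain_ids) < 2:
        return SymmetryModel(
            point_group="C1", order=1, principal_axis=np.array([0.0, 0.0, 1.0])
        )
    full = _detect_on_subset(assembly, chain_ids, angle_tol, residual_tol)
    if full is not None:
        return full

    # full assembly is C1: hunt for the highest-order group over any subset
    def group_order(m: SymmetryModel) -> int:
        return 2 * m.order if m.point_group.startswith("D") else m.order

    best: SymmetryModel | None = None
    best_ids: list[str] = []
    for size in range(len(chain_ids) - 1, 1, -1):
        if best is not None and group_order(best) >= size:
            break  # no smaller subset can host a higher-order group
        for sub in itertools.combinations(chain_ids, size):
            model = _detect_on_subset(assembly, list(sub), angle_tol, residual_tol)
            if model is not None and (best is None or group_order(model) > group_order(best)):
                best, best_ids = model, list(sub)

    c1 = SymmetryModel(
        point_group="C1", order=1, principal_axis=np.array([0.0, 0.0, 1.0])
    )
    if best is not None:
        c1.subset_group = best.point_group
        c1.subset_chains = best_ids
        c1.outlier_chains = [c for c in chain_ids if c not in best_ids]
        c1.principal_axis = best.principal_axis
        c1.secondary_axes = best.secondary_axes
        c1.fit_residual = best.fit_residual
    return c1


# ---------------------------------------------------------------------------
# Interface classification


def _interchain_contact_pairs(
    chain_a: Chain, chain_b: Chain, cutoff: float
) -> list[tuple[int, int]]:
    """(seq_num_a, seq_num_b) per heavy-atom pair below cutoff."""
    from scipy.spatial import cKDTree

    atoms_a = [
        (r.seq_num, a.coords)
        for r in chain_a.protein_residues()
        for a in r.atoms
        if a.element != "H"
    ]
    atoms_b = [
        (r.seq_num, a.coords)
        for r in chain_b.protein_residues()
        for a in r.atoms
        if a.element != "H"
    ]
    if not atoms_a or not atoms_b:
        return []
    tree_b = cKDTree(np.array([c for _, c in atoms_b]))
    pairs = []
    coords_a = np.array([c for _, c in atoms_a])
    for i, js in enumerate(tree_b.query_ball_point(coords_a, cutoff)):
        for j in js:
            pairs.append((atoms_a[i][0], atoms_b[j][0]))
    return pairs


def classify_interfaces(
    assembly: Assembly,
    terminal_regions: dict[str, RegionDefinition] | RegionDefinition,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_contact_pairs: int = DEFAULT_MIN_CONTACT_PAIRS,
    offsets: dict[str, int] | None = None,
) -> list[InterfaceLabel]:
    """Type every chain pair as end_to_end, side_by_side or none.

    A pair is in contact when at least ``min_contact_pairs`` inter-chain
    heavy-atom pairs lie below ``contact_cutoff``.  A contacting pair is
    ``end_to_end`` when more than half of those atom pairs have *both* atoms
    in the named C-terminal strand region(s); otherwise ``side_by_side``.
    ``terminal_regions`` is one region applied to all chains or a mapping of
    region name -> region (union taken).  ``offsets`` maps chain id to its
    numbering offset into the regions' scheme.
    """
    if isinstance(terminal_regions, RegionDefinition):
        regions = [terminal_regions]
    else:
        regions = list(terminal_regions.values())
    offsets = offsets or {}

    def in_terminal(seq_num: int, chain_id: str) -> bool:
        shifted = seq_num + offsets.get(chain_id, 0)
        return any(shifted in reg for reg in regions)

    chains = assembly.protein_chains()
    labels: list[InterfaceLabel] = []
    for ca, cb in itertools.combinations(chains, 2):
        pairs = _interchain_contact_pairs(ca, cb, contact_cutoff)
        warns: list[str] = []
        if len(pairs) < min_contact_pairs:
            labels.append(
                InterfaceLabel(
                    chain_pair=(ca.chain_id, cb.chain_id),
                    label="none",
                    contact_area_proxy=len(pairs),
                )
            )
            continue
        n_term = sum(
            1
            for sa, sb in pairs
            if in_terminal(sa, ca.chain_id) and in_terminal(sb, cb.chain_id)
        )
        frac = n_term / len(pairs)
        resolved = any(
            in_terminal(r.seq_num, ch.chain_id)
            for ch in (ca, cb)
            for r in ch.protein_residues()
        )
        if not resolved:
            warns.append(
                "terminal-strand region matched no residues; "
                "classification defaults to side_by_side"
            )
        labels.append(
            InterfaceLabel(
                chain_pair=(ca.chain_id, cb.chain_id),
                label="end_to_end" if frac > 0.5 else "side_by_side",
                contact_area_proxy=len(pairs),
                terminal_fraction=frac,
                warnings=warns,
            )
        )
    return labels
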