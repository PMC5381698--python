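"""Macromolecular structure I/O and the coordinate data model.

Structures are read with :mod:`gemmi` and converted into a small, explicit
in-memory model (:class:`Atom` / :class:`Residue` / :class:`Assembly`) that the
rest of the package operates on.  Author residue numbering, as deposited, is
canonical; mapping between isoform numbering schemes is an explicit integer
offset (e.g. the short-isoform chain of human UDP-glucose pyrophosphorylase is
11 residues behind the full-length isoform, offset +11).

Only the first model of a multi-model file is kept, and for alternate
conformations the highest-occupancy conformer wins (ties broken by altloc
letter), so downstream geometry always sees a single conformer per atom.
Ligands and other heteroatoms survive parsing but are flagged and excluded
from protein-only selections by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Assembly",
    "UnitCell",
    "RegionDefinition",
    "RegionSelection",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "resolve_region",
    "load_region_definitions",
    "BACKBONE_ATOMS",
    "HUGP2_TO_HUGP1_OFFSET",
]

#: Backbone heavy-atom names; every other heavy atom is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Documented numbering offset: short-isoform (hUGP2) seq_num + 11 = hUGP1 seq_num.
HUGP2_TO_HUGP1_OFFSET = 11

#: Residue names treated as solvent, never part of protein or ligand selections.
_SOLVENT_NAMES = frozenset({"HOH", "WAT", "DOD"})

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or written."""


@dataclass
class Atom:
    """A single heavy atom (hydrogens are absent from the target structures)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_ca(self) -> bool:
        return self.name == "CA"


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone]

    @property
    def is_protein(self) -> bool:
        return not self.is_hetero and self.res_name not in _SOLVENT_NAMES

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_protein]

    def residue(self, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        return None

    def ca_coords(self) -> dict[int, np.ndarray]:
        """seq_num -> Cα coordinates for protein residues with a Cα."""
        out: dict[int, np.ndarray] = {}
        for r in self.protein_residues():
            ca = r.ca
            if ca is not None:
                out[r.seq_num] = ca.coords
        return out


@dataclass
class UnitCell:
    """Crystallographic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {ang} outside (0, 180)")


@dataclass
class Assembly:
    """A multi-chain structure (one model) with optional crystal metadata.

    ``state_label`` records whether the coordinates are an apo or a
    product-bound form, which downstream comparison code uses for reporting
    only — no behaviour depends on the label.
    """

    id: str
    chains: list[Chain] = field(default_factory=list)
    state_label: str = "unknown"  # {apo, product_bound, unknown}
    unit_cell: UnitCell | None = None
    space_group: str | None = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in assembly {self.id}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.protein_residues()]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def all_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def heavy_coords(self, protein_only: bool = True) -> np.ndarray:
        pts = [
            a.coords
            for _, r, a in self.all_atoms()
            if (r.is_protein or not protein_only) and a.element != "H"
        ]
        if not pts:
            return np.empty((0, 3))
        return np.array(pts)


@dataclass(frozen=True)
class RegionDefinition:
    """A named, chain-agnostic residue region (inclusive ranges).

    ``numbering_scheme`` is a free tag naming the scheme the ranges are
    written in (e.g. ``"hUGP1"``); chains deposited in a different scheme are
    reconciled through the integer offset of :func:`resolve_region`.
    """

    name: str
    ranges: tuple[tuple[int, int], ...]
    numbering_scheme: str = ""

    def __post_init__(self) -> None:
        rs = tuple(tuple(map(int, r)) for r in self.ranges)
        object.__setattr__(self, "ranges", rs)
        for start, end in rs:
            if start > end:
                raise ValueError(f"region {self.name}: range {start}-{end} has start > end")
        flat = sorted(rs)
        for (s1, e1), (s2, e2) in zip(flat, flat[1:]):
            if s2 <= e1:
                raise ValueError(f"region {self.name}: overlapping ranges")

    def __contains__(self, seq_num: int) -> bool:
        return any(s <= seq_num <= e for s, e in self.ranges)

    def seq_nums(self) -> list[int]:
        return [n for s, e in sorted(self.ranges) for n in range(s, e + 1)]


@dataclass
class RegionSelection:
    """Residues of one chain matched by a region, plus what was missing."""

    region: RegionDefinition
    chain_id: str
    offset: int
    residues: list[Residue]
    missing_seq_nums: list[int]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


# ---------------------------------------------------------------------------
# Reading


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_structure(
    path: str | Path,
    fmt: str = "auto",
    state_label: str = "unknown",
) -> Assembly:
    """Read a PDB or mmCIF file into an :class:`Assembly`.

    Parameters
    ----------
    path:
        Structure file.  ``fmt`` may be ``"pdb"``, ``"mmcif"`` or ``"auto"``
        (extension-based detection, gemmi's default behaviour).
    state_label:
        Provenance tag carried on the returned assembly
        (``apo`` / ``product_bound`` / ``unknown``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureFormatError(f"cannot parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise StructureFormatError(f"{path.name}: no models")
    st.setup_entities()
    model = st[0]  # first model only: crystal structures here are single-model

    chains: list[Chain] = []
    serial = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            het = gres.het_flag == "H"
            atoms: list[Atom] = []
            seen: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                seen.setdefault(ga.name, []).append(ga)
            for name, group in seen.items():
                ga = _pick_altloc(group)
                serial += 1
                atoms.append(
                    Atom(
                        serial=ga.serial or serial,
                        name=name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_factor=ga.b_iso,
                        altloc=ga.altloc.strip() if ga.altloc else "",
                    )
                )
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_num=gres.seqid.num,
                    res_name=gres.name,
                    icode=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                    is_hetero=het and gres.name not in _STANDARD_AA,
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise StructureFormatError(f"{path.name}: first model is empty")

    cell = None
    if st.cell and st.cell.a > 1.0:  # gemmi uses a dummy 1 Å cell when absent
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    return Assembly(
        id=st.name or path.stem,
        chains=chains,
        state_label=state_label,
        unit_cell=cell,
        space_group=st.spacegroup_hm or None,
    )


# ---------------------------------------------------------------------------
# Writing


_PDB_COORD_LIMIT = 9999.999  # fixed 8.3 field


def write_structure(assembly: Assembly, path: str | Path, fmt: str = "pdb") -> Path:
    """Write an assembly as a PDB file (fixed-width, 3-decimal coordinates)."""
    if fmt != "pdb":
        raise ValueError(f"unsupported output format {fmt!r}")
    if assembly.n_atoms() == 0:
        raise ValueError("refusing to write an assembly with no atoms")
    for _, _, a in assembly.all_atoms():
        if np.any(np.abs(a.coords) > _PDB_COORD_LIMIT):
            raise StructureFormatError(
                f"coordinate {a.coords} exceeds the PDB fixed-width field"
            )

    st = gemmi.Structure()
    st.name = assembly.id
    if assembly.unit_cell is not None:
        uc = assembly.unit_cell
        st.cell = gemmi.UnitCell(uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma)
    if assembly.space_group:
        st.spacegroup_hm = assembly.space_group
    model = gemmi.Model("1")
    serial = 0
    for chain in assembly.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                serial += 1
                ga.serial = serial
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Region resolution


def resolve_region(
    assembly: Assembly,
    region: RegionDefinition,
    chain_id: str,
    offset: int = 0,
) -> RegionSelection:
    """Select the residues of ``chain_id`` matched by ``region``.

    A chain residue matches when ``seq_num + offset`` falls inside one of the
    region's ranges, so a region written in one numbering scheme can be applied
    to a chain deposited in another by passing the documented offset.  Region
    positions with no corresponding residue (disordered loops, truncations)
    are reported in ``missing_seq_nums`` rather than silently dropped; an
    empty selection carries a warning instead of raising.
    """
    chain = assembly.chain(chain_id)
    matched: list[Residue] = []
    found: set[int] = set()
    for res in chain.protein_residues():
        shifted = res.seq_num + offset
        if shifted in region:
            matched.append(res)
            found.add(shifted)
    missing = [n for n in region.seq_nums() if n not in found]
    warns: list[str] = []
    if not matched:
        msg = (
            f"region {region.name!r} matched no residues on chain {chain_id} "
            f"(offset {offset:+d})"
        )
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    elif missing:
        warns.append(
            f"region {region.name!r} on chain {chain_id}: missing residues {missing}"
        )
    return RegionSelection(
        region=region,
        chain_id=chain_id,
        offset=offset,
        residues=matched,
        missing_seq_nums=missing,
        warnings=warns,
    )


def load_region_definitions(path: str | Path) -> dict[str, RegionDefinition]:
    """Load named regions from a small YAML/JSON config file.

    Expected layout::

        SB-loop:
          ranges: [[286, 293]]
          scheme: hUGP1
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of region name -> definition")
    out: dict[str, RegionDefinition] = {}
    for name, body in raw.items():
        if isinstance(body, dict):
            ranges = body.get("ranges", [])
            scheme = body.get("scheme", "")
        else:  # allow the terse form  name: [[s, e], ...]
            ranges, scheme = body, ""
        out[name] = RegionDefinition(
            name=name, ranges=tuple(tuple(r) for r in ranges), numbering_scheme=scheme
        )
    return out
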