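"""Periodic crystal structures and the geometry primitives built on them.

Conventions used throughout the package: fractional coordinates wrapped to
[0, 1); Cartesian coordinates in Angstrom; the lattice matrix has the three
lattice vectors as rows, so ``cart = frac @ matrix``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from gemmi import cif as gemmi_cif
import gemmi

from .elements import (
    ElementError,
    atomic_mass,
    covalent_radius,
    is_known_element,
)

__all__ = [
    "UnitCell",
    "AtomSite",
    "PeriodicStructure",
    "SmallMolecule",
    "CifFormatError",
    "EmptyStructureError",
    "DisorderError",
    "parse_cif",
    "write_cif",
    "min_image_distance",
    "build_supercell",
    "perceive_bonds",
    "periodic_bonds",
    "BOND_TOLERANCE",
]

#: Added to the sum of covalent radii when perceiving bonds (Angstrom).
BOND_TOLERANCE = 0.45

#: Two symmetry images closer than this are merged as duplicates (Angstrom).
DUPLICATE_SITE_THRESHOLD = 0.1


class CifFormatError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


class DisorderError(ValueError):
    """Raised for partially occupied sites; disordered frameworks are out of scope."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        if self._v_factor() <= 0:
            raise ValueError("cell angles give non-positive volume")

    def _v_factor(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return math.sqrt(arg) if arg > 0 else -1.0

    @property
    def matrix(self) -> np.ndarray:
        """3x3 lattice matrix, lattice vectors as rows (Angstrom)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self._v_factor()
        return np.array([
            [self.a, 0.0, 0.0],
            [self.b * cg, self.b * sg, 0.0],
            [self.c * cb, self.c * (ca - cb * cg) / sg, self.c * v / sg],
        ])

    @property
    def volume(self) -> float:
        """Cell volume in Angstrom^3 (analytic triclinic formula)."""
        return self.a * self.b * self.c * self._v_factor()

    @property
    def perpendicular_widths(self) -> np.ndarray:
        """Perpendicular width along each lattice direction (Angstrom).

        Width_i = V / |a_j x a_k|; the minimum-image convention at cutoff
        r_c is valid when every width is >= 2 r_c.
        """
        m = self.matrix
        widths = np.empty(3)
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            widths[i] = self.volume / np.linalg.norm(np.cross(m[j], m[k]))
        return widths

    def frac_to_cart(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def cart_to_frac(self, cart) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.matrix)

    @property
    def is_orthogonal(self) -> bool:
        return all(abs(x - 90.0) < 1e-9 for x in (self.alpha, self.beta, self.gamma))


def _wrap(frac) -> np.ndarray:
    f = np.asarray(frac, dtype=float) % 1.0
    # guard against 1.0 surviving the modulo through rounding
    f[f >= 1.0] -= 1.0
    return f


@dataclass(frozen=True)
class AtomSite:
    element: str
    frac: tuple[float, float, float]
    charge: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not is_known_element(self.element):
            raise ElementError(f"unrecognized element symbol {self.element!r}")
        object.__setattr__(self, "frac", tuple(_wrap(np.asarray(self.frac))))


@dataclass
class PeriodicStructure:
    """A periodic crystal: unit cell plus an ordered list of atom sites."""

    cell: UnitCell
    sites: list[AtomSite]
    name: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites]).reshape(-1, 3)

    @property
    def cart_coords(self) -> np.ndarray:
        return self.cell.frac_to_cart(self.frac_coords)

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    @property
    def mass_per_cell(self) -> float:
        """Framework molar mass per unit cell (g/mol)."""
        return float(sum(atomic_mass(s.element) for s in self.sites))


@dataclass
class SmallMolecule:
    """A finite molecule: explicit atoms with Cartesian coordinates and bonds.

    ``atoms`` is a list of (element, xyz Angstrom, partial charge e);
    ``bonds`` a list of (i, j, order).
    """

    atoms: list[tuple[str, np.ndarray, float]]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    net_charge: int = 0
    notation: str | None = None

    def __post_init__(self):
        n = len(self.atoms)
        self.atoms = [(el, np.asarray(xyz, dtype=float), float(q)) for el, xyz, q in self.atoms]
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError("self-loop bond")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a[0] for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms])

    @property
    def molar_mass(self) -> float:
        return float(sum(atomic_mass(el) for el in self.elements))


# ---------------------------------------------------------------------------
# CIF I/O
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?\d*\.?\d+(?:[eE][+-]?\d+)?")
_ELEM_RE = re.compile(r"^([A-Z][a-z]?)")


def _cif_float(text: str) -> float:
    """Parse a CIF numeric field, stripping the '(5)' uncertainty suffix."""
    m = _NUM_RE.match(text.strip())
    if not m:
        raise CifFormatError(f"cannot parse CIF number {text!r}")
    return float(m.group(0))


def _element_from_symbol(symbol: str) -> str:
    """Strip oxidation-state suffixes: 'Zr4+' -> 'Zr', 'O2-' -> 'O'."""
    m = _ELEM_RE.match(symbol.strip())
    if not m:
        raise ElementError(f"cannot parse element from {symbol!r}")
    el = m.group(1)
    if not is_known_element(el):
        # labels like 'Cd1' match two letters; retry with one
        if is_known_element(el[:1]):
            return el[:1]
        raise ElementError(f"unrecognized element symbol {symbol!r}")
    return el


def parse_cif(text: str, name: str | None = None) -> PeriodicStructure:
    """Parse a CIF document into a :class:`PeriodicStructure`.

    Symmetry operators (``_symmetry_equiv_pos_as_xyz`` or
    ``_space_group_symop_operation_xyz``) are applied and duplicate images
    closer than 0.1 Angstrom are merged; if neither tag is present the cell
    is taken as P1.  Sites with occupancy < 1 are rejected.
    """
    try:
        doc = gemmi_cif.read_string(text)
        block = doc.sole_block() if len(doc) == 1 else doc[0]
    except Exception as exc:
        raise CifFormatError(f"unreadable CIF document: {exc}") from exc

    def cell_param(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise CifFormatError(f"missing cell parameter {tag}")
        return _cif_float(val)

    cell = UnitCell(
        a=cell_param("_cell_length_a"),
        b=cell_param("_cell_length_b"),
        c=cell_param("_cell_length_c"),
        alpha=cell_param("_cell_angle_alpha"),
        beta=cell_param("_cell_angle_beta"),
        gamma=cell_param("_cell_angle_gamma"),
    )

    ops: list[gemmi.Op] = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        triplets = list(col) if col else []
        if not triplets:
            val = block.find_value(tag)
            if val is not None:
                triplets = [val]
        if triplets:
            ops = [gemmi.Op(gemmi_cif.as_string(t)) for t in triplets]
            break
    if not ops:
        ops = [gemmi.Op("x,y,z")]

    sym_col = None
    for sym_tag in ("_atom_site_type_symbol", "_atom_site_label"):
        sym_col = block.find_loop(sym_tag)
        if sym_col:
            break
    fx = block.find_loop("_atom_site_fract_x")
    fy = block.find_loop("_atom_site_fract_y")
    fz = block.find_loop("_atom_site_fract_z")
    occ = block.find_loop("_atom_site_occupancy")
    labels = block.find_loop("_atom_site_label")
    if not (sym_col and fx and fy and fz):
        raise CifFormatError("missing atom-site loop with type symbol and fractional coordinates")
    symbols = list(sym_col)
    if len(symbols) == 0:
        raise EmptyStructureError("atom-site loop is empty")

    occ_list = list(occ) if occ else []
    label_list = [gemmi_cif.as_string(v) for v in labels] if labels else [""] * len(symbols)

    sites: list[AtomSite] = []
    frac_seen: list[np.ndarray] = []
    for idx, (sym, x, y, z) in enumerate(zip(symbols, list(fx), list(fy), list(fz))):
        if occ_list:
            o = _cif_float(occ_list[idx]) if occ_list[idx] not in (".", "?") else 1.0
            if o < 1.0 - 1e-6:
                raise DisorderError(
                    f"site {idx} has occupancy {o} < 1; disordered structures are not supported"
                )
        element = _element_from_symbol(gemmi_cif.as_string(sym))
        base = np.array([_cif_float(x), _cif_float(y), _cif_float(z)])
        for op in ops:
            img = _wrap(np.array(op.apply_to_xyz(list(base))))
            if any(
                min_image_distance(cell, img, prev) < DUPLICATE_SITE_THRESHOLD
                for prev in frac_seen
            ):
                continue
            frac_seen.append(img)
            sites.append(AtomSite(element=element, frac=tuple(img), label=label_list[idx]))

    if not sites:
        raise EmptyStructureError("no atom sites after symmetry expansion")
    block_name = name if name is not None else (block.name or "")
    return PeriodicStructure(cell=cell, sites=sites, name=block_name)


def write_cif(structure: PeriodicStructure) -> str:
    """Serialize a structure as a P1 CIF document (no symmetry compression)."""
    cell = structure.cell
    name = structure.name.strip().replace(" ", "_") or "structure"
    lines = [
        f"data_{name}",
        "_symmetry_space_group_name_H-M    'P 1'",
        "_symmetry_Int_Tables_number       1",
        f"_cell_length_a     {cell.a:.6f}",
        f"_cell_length_b     {cell.b:.6f}",
        f"_cell_length_c     {cell.c:.6f}",
        f"_cell_angle_alpha  {cell.alpha:.6f}",
        f"_cell_angle_beta   {cell.beta:.6f}",
        f"_cell_angle_gamma  {cell.gamma:.6f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    counts: dict[str, int] = {}
    for site in structure.sites:
        counts[site.element] = counts.get(site.element, 0) + 1
        label = site.label or f"{site.element}{counts[site.element]}"
        x, y, z = site.frac
        lines.append(
            f"{label} {site.element} {x:.6f} {y:.6f} {z:.6f} 1.0"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

_SHIFTS_27 = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)


def min_image_distance(cell: UnitCell, frac_p, frac_q) -> float:
    """Minimum distance between two fractional points over the 27 nearest images.

    Exact whenever the cell's perpendicular widths are at least twice the
    distance of interest (always true for bond-length scales in the cells
    this package handles).
    """
    d = _wrap(frac_q) - _wrap(frac_p)
    vecs = (d + _SHIFTS_27) @ cell.matrix
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", vecs, vecs))))


def build_supercell(structure: PeriodicStructure, min_width: float) -> PeriodicStructure:
    """Replicate the cell so every perpendicular width is >= ``min_width``."""
    if min_width <= 0:
        raise ValueError("min_width must be > 0")
    widths = structure.cell.perpendicular_widths
    reps = np.maximum(1, np.ceil(min_width / widths - 1e-12).astype(int))
    if tuple(reps) == (1, 1, 1):
        return replace(structure)
    cell = structure.cell
    new_cell = UnitCell(
        a=cell.a * reps[0], b=cell.b * reps[1], c=cell.c * reps[2],
        alpha=cell.alpha, beta=cell.beta, gamma=cell.gamma,
    )
    sites = []
    for ia in range(reps[0]):
        for ib in range(reps[1]):
            for ic in range(reps[2]):
                off = np.array([ia, ib, ic], dtype=float)
                for s in structure.sites:
                    frac = (np.asarray(s.frac) + off) / reps
                    sites.append(AtomSite(s.element, tuple(frac), s.charge, s.label))
    return PeriodicStructure(cell=new_cell, sites=sites,
                             name=f"{structure.name}_{reps[0]}x{reps[1]}x{reps[2]}")


def periodic_bonds(
    structure: PeriodicStructure, tolerance: float = BOND_TOLERANCE
) -> list[tuple[int, int, np.ndarray]]:
    """Perceive bonds in a periodic structure.

    Returns (i, j, shift) triples with i < j, where ``shift`` is the integer
    lattice translation such that site j's bonded image sits at
    ``frac_j + shift`` relative to site i.  Criterion: minimum-image distance
    <= r_cov(i) + r_cov(j) + tolerance.
    """
    frac = structure.frac_coords
    radii = np.array([covalent_radius(el) for el in structure.elements])
    n = len(frac)
    bonds: list[tuple[int, int, np.ndarray]] = []
    max_bond = 2 * radii.max() + tolerance
    if np.any(structure.cell.perpendicular_widths < 2 * max_bond):
        # tiny cells: a site can bond to several images of the same partner;
        # enumerate the 27 shifts explicitly
        shift_list = _SHIFTS_27
    else:
        shift_list = None
    for i in range(n):
        d = frac[i + 1:] - frac[i]
        if shift_list is None:
            shift = -np.round(d)
            vec = (d + shift) @ structure.cell.matrix
            dist = np.linalg.norm(vec, axis=1)
            cut = radii[i] + radii[i + 1:] + tolerance
            for k in np.nonzero(dist <= cut)[0]:
                bonds.append((i, i + 1 + k, shift[k].astype(int)))
        else:
            for k in range(len(d)):
                vecs = (d[k] + shift_list) @ structure.cell.matrix
                dist = np.sqrt(np.einsum("ij,ij->i", vecs, vecs))
                cut = radii[i] + radii[i + 1 + k] + tolerance
                m = int(np.argmin(dist))
                if dist[m] <= cut:
                    bonds.append((i, i + 1 + k, shift_list[m].astype(int)))
    return bonds


def perceive_bonds(obj, tolerance: float = BOND_TOLERANCE):
    """Perceive bonds by covalent-radius sum + tolerance.

    For a :class:`PeriodicStructure` returns (i, j, shift) triples under the
    minimum-image convention; for a :class:`SmallMolecule` returns plain
    (i, j) pairs from Cartesian distances.
    """
    if isinstance(obj, PeriodicStructure):
        return periodic_bonds(obj, tolerance)
    if isinstance(obj, SmallMolecule):
        coords = obj.coords
        radii = np.array([covalent_radius(el) for el in obj.elements])
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        cut = radii[:, None] + radii[None, :] + tolerance
        pairs = []
        n = len(coords)
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] <= cut[i, j]:
                    pairs.append((i, j))
        return pairs
    raise TypeError(f"cannot perceive bonds on {type(obj).__name__}")
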