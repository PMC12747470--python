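"""Pore-geometry descriptors: PLD, LCD, pore-size distribution, pore volume.

All descriptors derive from a periodic distance grid: at each grid point,
the distance to the nearest framework-atom van der Waals surface (negative
inside an atom).  The largest cavity diameter (LCD) is twice the maximum
grid value.  The pore-limiting diameter (PLD) is the largest probe diameter
whose void set contains a component that percolates — connects a point to
its own periodic image along at least one lattice direction — found by
bisection over connected-component analysis with periodic wrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .elements import vdw_radius
from .structures import PeriodicStructure

__all__ = [
    "DistanceGrid",
    "compute_distance_grid",
    "largest_cavity_diameter",
    "pore_limiting_diameter",
    "pore_size_distribution",
    "accessible_pore_volume",
    "porosity_filter",
    "PoreDescriptors",
    "compute_pore_descriptors",
]

AVOGADRO = 6.02214076e23


@dataclass
class DistanceGrid:
    """Distance-to-surface samples on a regular fractional grid."""

    values: np.ndarray  # (na, nb, nc): distance to nearest vdW surface, Angstrom
    cell_matrix: np.ndarray
    spacing: float  # requested maximum spacing, Angstrom

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def axis_spacings(self) -> np.ndarray:
        """Actual grid step along each lattice vector (Angstrom)."""
        lengths = np.linalg.norm(self.cell_matrix, axis=1)
        return lengths / np.array(self.values.shape)


def _atom_tree(structure: PeriodicStructure):
    """KDTree over framework atoms tiled into the 27 neighbor images, grouped by radius."""
    frac = structure.frac_coords
    radii = np.array([vdw_radius(el) for el in structure.elements])
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
    )
    groups = []
    for r in np.unique(radii):
        sel = frac[radii == r]
        tiled = (sel[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
        carts = tiled @ structure.cell.matrix
        groups.append((float(r), cKDTree(carts)))
    return groups


def _surface_distance(points_cart: np.ndarray, groups) -> np.ndarray:
    """min over atoms of (|p - atom| - r_vdw); vectorized over points."""
    best = np.full(len(points_cart), np.inf)
    for r, tree in groups:
        d, _ = tree.query(points_cart, k=1)
        np.minimum(best, d - r, out=best)
    return best


def compute_distance_grid(
    structure: PeriodicStructure, spacing: float = 0.5
) -> DistanceGrid:
    """Periodic distance transform of the framework's van der Waals surface."""
    if structure.n_sites == 0:
        raise ValueError("cannot grid an empty structure")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    m = structure.cell.matrix
    lengths = np.linalg.norm(m, axis=1)
    dims = np.maximum(2, np.ceil(lengths / spacing).astype(int))
    fa, fb, fc = (np.arange(n) / n for n in dims)
    frac = np.stack(np.meshgrid(fa, fb, fc, indexing="ij"), axis=-1).reshape(-1, 3)
    carts = frac @ m
    groups = _atom_tree(structure)
    values = _surface_distance(carts, groups).reshape(tuple(dims))
    return DistanceGrid(values=values, cell_matrix=m, spacing=spacing)


def largest_cavity_diameter(grid: DistanceGrid) -> float:
    """Diameter of the largest sphere fitting anywhere in the void (Angstrom)."""
    return float(max(0.0, 2.0 * grid.values.max()))


# ---------------------------------------------------------------------------
# Periodic percolation
# ---------------------------------------------------------------------------


class _OffsetUnionFind:
    """Union-find over component labels carrying integer lattice offsets.

    ``offset[l]`` is the lattice translation from label l's local frame to
    its root's frame.  Merging two labels already sharing a root with an
    inconsistent required offset means the component connects to its own
    periodic image: it percolates, with wrap vector = the discrepancy.
    """

    def __init__(self, n: int):
        self.parent = list(range(n + 1))
        self.offset = np.zeros((n + 1, 3), dtype=int)
        self.wraps: set[tuple[int, int, int]] = set()
        self.wrap_roots: set[int] = set()

    def _root_offset(self, a: int) -> tuple[int, np.ndarray]:
        off = np.zeros(3, dtype=int)
        while self.parent[a] != a:
            off += self.offset[a]
            a = self.parent[a]
        return a, off

    def union(self, a: int, b: int, delta: np.ndarray):
        """Record frame(b) = frame(a) + delta."""
        ra, offa = self._root_offset(a)
        rb, offb = self._root_offset(b)
        if ra == rb:
            wrap = offa + delta - offb
            if np.any(wrap != 0):
                self.wraps.add(tuple(int(v) for v in wrap))
                self.wrap_roots.add(ra)
            return
        # attach rb under ra: offset[rb] = frame-shift from rb to ra
        self.parent[rb] = ra
        self.offset[rb] = offa + delta - offb


def _percolation(mask: np.ndarray):
    """Label a periodic boolean grid; return (labels, percolating root set, uf).

    Percolating components are those connecting to their own periodic image
    along at least one lattice direction.
    """
    labels, n = ndimage.label(mask)
    uf = _OffsetUnionFind(n)
    if n == 0:
        return labels, set(), uf
    for axis in range(3):
        first = np.take(labels, 0, axis=axis)
        last = np.take(labels, -1, axis=axis)
        pair = (first > 0) & (last > 0)
        if not pair.any():
            continue
        delta = np.zeros(3, dtype=int)
        delta[axis] = 1
        la, lb = last[pair].ravel(), first[pair].ravel()
        for a, b in set(zip(la.tolist(), lb.tolist())):
            # the first-slab cell is the last-slab cell's neighbor one cell over
            uf.union(a, b, delta)
    percolating: set[int] = set()
    for l in range(1, n + 1):
        root, _ = uf._root_offset(l)
        if root in uf.wrap_roots:
            percolating.add(l)
    return labels, percolating, uf


def pore_limiting_diameter(grid: DistanceGrid) -> float:
    """Largest probe diameter that can percolate through the void network."""
    vals = np.unique(grid.values[grid.values > 0])
    if vals.size == 0:
        return 0.0

    def percolates(radius: float) -> bool:
        _, perc, _ = _percolation(grid.values >= radius)
        return len(perc) > 0

    if not percolates(vals[0]):
        return 0.0
    lo, hi = 0, vals.size - 1  # invariant: percolates at lo, test up to hi
    if percolates(vals[hi]):
        return float(2 * vals[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if percolates(vals[mid]):
            lo = mid
        else:
            hi = mid
    return float(2 * vals[lo])


# ---------------------------------------------------------------------------
# Pore-size distribution
# ---------------------------------------------------------------------------


def _periodic_edt(mask: np.ndarray, sampling) -> np.ndarray:
    """Distance from each cell to the nearest True cell, with periodic wrap.

    Tiles the grid 3x along each axis and reads back the central block;
    exact for features smaller than one cell (always true for pore radii).
    """
    tiled = np.tile(mask, (3, 3, 3))
    dist = ndimage.distance_transform_edt(~tiled, sampling=sampling)
    na, nb, nc = mask.shape
    return dist[na:2 * na, nb:2 * nb, nc:2 * nc]


def pore_size_distribution(
    grid: DistanceGrid, bin_width: float = 1.0, weight_threshold: float = 0.02
) -> list[tuple[float, float]]:
    """Histogram of largest-covering-sphere diameters over void grid points.

    A void point's covering diameter is the largest sphere diameter d such
    that some sphere of diameter >= d contains the point while fitting in
    the void; computed by descending over diameter bins with the identity
    "p is covered at d iff dist(p, {value >= d/2}) <= d/2" (periodic
    Euclidean distance transform).  Requires an orthogonal cell (the EDT
    metric is separable per axis).

    Returns PSD peaks: local maxima of the histogram with weight fraction
    >= ``weight_threshold``, as (diameter, weight fraction), sorted by
    descending diameter.
    """
    mat = grid.cell_matrix
    off_diag = mat - np.diag(np.diag(mat))
    if np.abs(off_diag).max() > 1e-6:
        raise ValueError("pore_size_distribution requires an orthogonal cell")
    sampling = grid.axis_spacings
    void = grid.values > 0
    n_void = int(void.sum())
    if n_void == 0:
        return []
    lcd = largest_cavity_diameter(grid)
    edges = np.arange(np.ceil(lcd / bin_width) * bin_width, 0.0, -bin_width)
    covered = np.zeros_like(void)
    hist: dict[float, int] = {}
    # a sphere center falling between grid points is seen too small by up to
    # half a grid diagonal (the distance-grid error bound); compensate
    half_h = float(np.linalg.norm(sampling)) / 2
    for d in edges:
        centers = grid.values >= d / 2 - half_h
        if not centers.any():
            continue
        dist = _periodic_edt(centers, sampling)
        newly = void & ~covered & (dist <= d / 2 + 1e-9)
        cnt = int(newly.sum())
        if cnt:
            hist[float(d)] = cnt
            covered |= newly
        if covered[void].all():
            break
    # local maxima over the descending-diameter histogram
    diams = sorted(hist, reverse=True)
    weights = [hist[d] / n_void for d in diams]
    peaks = []
    for k, (d, w) in enumerate(zip(diams, weights)):
        if w < weight_threshold:
            continue
        left = weights[k - 1] if k > 0 else 0.0
        right = weights[k + 1] if k + 1 < len(weights) else 0.0
        # bins adjacent in the sorted list may not be adjacent diameters;
        # treat gaps (empty bins) as zero weight
        if k > 0 and abs(diams[k - 1] - d) > bin_width * 1.5:
            left = 0.0
        if k + 1 < len(diams) and abs(diams[k + 1] - d) > bin_width * 1.5:
            right = 0.0
        if w >= left and w >= right:
            peaks.append((d, w))
    return peaks


# ---------------------------------------------------------------------------
# Accessible pore volume
# ---------------------------------------------------------------------------


def accessible_pore_volume(
    structure: PeriodicStructure,
    probe_radius: float = 0.0,
    samples: int = 20000,
    seed: int = 0,
    accessible_only: bool = True,
    grid: DistanceGrid | None = None,
    grid_spacing: float = 0.5,
) -> tuple[float, float, float]:
    """Monte-Carlo guest-accessible pore volume.

    Inserts a hard-sphere probe at ``samples`` uniform random fractional
    points; the fraction with clearance >= ``probe_radius`` is the void
    fraction, converted to cm^3 per gram of framework.  With
    ``accessible_only`` (default) only points lying in a void component
    that percolates at the probe radius are counted, so isolated pockets a
    guest cannot reach are excluded.

    Returns (volume cm^3/g, void fraction, binomial standard error of the
    void fraction).
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    mass = structure.mass_per_cell
    if structure.n_sites == 0:
        # atom-free box: void fraction 1 by definition, per-gram volume undefined
        return math.inf, 1.0, 0.0
    if mass <= 0:
        raise ValueError("zero-mass structure")
    rng = np.random.default_rng(seed)
    frac = rng.random((samples, 3))
    carts = frac @ structure.cell.matrix
    groups = _atom_tree(structure)
    clearance = _surface_distance(carts, groups)
    ok = clearance >= probe_radius
    if accessible_only:
        if grid is None:
            grid = compute_distance_grid(structure, spacing=grid_spacing)
        labels, percolating, _ = _percolation(grid.values >= probe_radius)
        if percolating:
            idx = np.floor(frac * np.array(grid.dims)).astype(int) % np.array(grid.dims)
            pt_labels = labels[idx[:, 0], idx[:, 1], idx[:, 2]]
            in_perc = np.isin(pt_labels, list(percolating))
            ok = ok & in_perc
        else:
            ok = np.zeros_like(ok)
    void_fraction = float(ok.mean())
    se = float(np.sqrt(max(void_fraction * (1 - void_fraction), 1e-12) / samples))
    volume_cm3_per_g = (
        void_fraction * structure.cell.volume * 1e-24 * AVOGADRO / mass
    )
    return volume_cm3_per_g, void_fraction, se


# ---------------------------------------------------------------------------
# Descriptor bundle and porosity filter
# ---------------------------------------------------------------------------


@dataclass
class PoreDescriptors:
    pld: float
    lcd: float
    psd_peaks: list[tuple[float, float]]
    accessible_volume: float  # cm^3/g at probe_radius
    void_fraction: float
    probe_radius: float
    porous: bool
    grid_spacing: float = 0.5
    extras: dict = field(default_factory=dict)


def porosity_filter(descriptors: PoreDescriptors, guest_min_diameter: float) -> bool:
    """True iff the guest can enter: PLD >= its minimal diameter (inclusive)
    and there is accessible volume."""
    return (
        descriptors.pld >= guest_min_diameter and descriptors.accessible_volume > 0
    )


def compute_pore_descriptors(
    structure: PeriodicStructure,
    spacing: float = 0.5,
    probe_radius: float = 0.0,
    samples: int = 20000,
    seed: int = 0,
    psd: bool = False,
    psd_bin_width: float = 1.0,
) -> PoreDescriptors:
    """One-stop computation of the descriptor bundle for a framework."""
    grid = compute_distance_grid(structure, spacing=spacing)
    lcd = largest_cavity_diameter(grid)
    pld = pore_limiting_diameter(grid)
    peaks = (
        pore_size_distribution(grid, bin_width=psd_bin_width)
        if psd and lcd > 0 and structure.cell.is_orthogonal
        else []
    )
    vol, vf, se = accessible_pore_volume(
        structure,
        probe_radius=probe_radius,
        samples=samples,
        seed=seed,
        grid=grid,
    )
    return PoreDescriptors(
        pld=pld,
        lcd=lcd,
        psd_peaks=peaks,
        accessible_volume=vol,
        void_fraction=vf,
        probe_radius=probe_radius,
        porous=pld >= 2 * probe_radius and vol > 0,
        grid_spacing=spacing,
        extras={"void_fraction_se": se},
    )
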