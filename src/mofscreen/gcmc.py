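"""Grand canonical Monte Carlo estimation of drug-loading capacity.

Rigid guest molecules in a rigid periodic framework, 12-6 Lennard-Jones
interactions with Lorentz-Berthelot mixing, fugacity-form acceptance rules:

    insert:  min(1, (beta f V / (N+1)) exp(-beta dU))
    delete:  min(1, (N / (beta f V))  exp(-beta dU))
    move:    min(1, exp(-beta dU))

Energies are in kelvin (epsilon / k_B convention), so beta dU = dU / T.
The framework is replicated until every perpendicular cell width is at
least twice the cutoff, which makes the minimum-image convention exact.
Uptake converts to mg drug per g framework and to wt.% of total mass
(1000 mg/g = 50 wt.%).

A lattice-gas mode (independent adsorption sites, closed-form Langmuir
isotherm) provides an exactly solvable system for validating the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import PeriodicStructure, build_supercell

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ForceField",
    "RigidGuest",
    "GCMCConfig",
    "GCMCResult",
    "lj_pair_energy",
    "run_gcmc",
    "widom_henry",
    "run_lattice_gcmc",
    "lattice_isotherm",
    "loading_conversions",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass
class ForceField:
    """Per-type 12-6 LJ parameters: epsilon in K, sigma in Angstrom."""

    params: dict[str, tuple[float, float]]
    cutoff: float = 12.8
    shifted: bool = False

    def __post_init__(self):
        for t, (eps, sig) in self.params.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"invalid LJ parameters for type {t!r}")

    def mixed(self, type_i: str, type_j: str) -> tuple[float, float]:
        """Lorentz-Berthelot mixing: arithmetic sigma, geometric epsilon."""
        try:
            ei, si = self.params[type_i]
            ej, sj = self.params[type_j]
        except KeyError as exc:
            raise KeyError(f"no LJ parameters for type {exc.args[0]!r}") from exc
        return math.sqrt(ei * ej), 0.5 * (si + sj)


def lj_pair_energy(type_i: str, type_j: str, r: float, ff: ForceField) -> float:
    """12-6 LJ pair energy in K; 0 beyond the cutoff, +inf at r = 0."""
    if r <= 0:
        return math.inf
    if r >= ff.cutoff:
        return 0.0
    eps, sig = ff.mixed(type_i, type_j)
    x6 = (sig / r) ** 6
    u = 4.0 * eps * (x6 * x6 - x6)
    if ff.shifted:
        xc6 = (sig / ff.cutoff) ** 6
        u -= 4.0 * eps * (xc6 * xc6 - xc6)
    return u


@dataclass
class RigidGuest:
    """Rigid guest model: LJ sites in a body frame centered at the centroid."""

    name: str
    sites: list[tuple[str, tuple[float, float, float], float]]  # (type, xyz A, charge e)
    molar_mass: float

    def __post_init__(self):
        if not self.sites:
            raise ValueError("guest needs at least one site")
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        coords = np.array([s[1] for s in self.sites], dtype=float)
        coords -= coords.mean(axis=0)
        self.sites = [
            (t, tuple(xyz), q) for (t, _, q), xyz in zip(self.sites, coords)
        ]

    @property
    def body_coords(self) -> np.ndarray:
        return np.array([s[1] for s in self.sites])

    @property
    def site_types(self) -> list[str]:
        return [s[0] for s in self.sites]

    def minimal_diameter(self, ff: ForceField) -> float:
        """Smallest projection width governing pore entry (Angstrom).

        Approximated as the middle eigen-extent of the site cloud plus the
        largest site sigma as van der Waals padding.
        """
        pad = max(ff.params[t][1] for t in self.site_types)
        coords = self.body_coords
        if len(coords) == 1:
            return pad
        cov = np.cov(coords.T)
        _, vecs = np.linalg.eigh(np.atleast_2d(cov))
        proj = coords @ vecs
        extents = proj.max(axis=0) - proj.min(axis=0)
        return float(np.sort(extents)[1] + pad)


@dataclass
class GCMCConfig:
    temperature: float = 298.0  # K
    fugacity: float = 1e5  # Pa
    move_probabilities: tuple[float, float, float, float] = (0.25, 0.25, 0.4, 0.1)
    cycles: int = 20000  # production MC steps
    equilibration: int = 5000
    max_translation: float = 1.0  # Angstrom, auto-tuned during equilibration
    seed: int = 0
    min_box_width: float = 0.0  # extra minimum supercell width (Angstrom)
    n_blocks: int = 10

    def __post_init__(self):
        p = self.move_probabilities
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if abs(p[0] - p[1]) > 1e-12:
            raise ValueError("insert and delete probabilities must be equal")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.cycles <= 0 or self.equilibration < 0:
            raise ValueError("cycles must be positive")


@dataclass
class GCMCResult:
    mean_n: float
    mean_n_se: float
    var_n: float  # production-run variance of N (Poisson: var = mean)
    loading_mg_per_g: float
    loading_wt_percent: float
    acceptance_rates: dict[str, float]
    mean_energy: float  # K
    framework_mass_box: float  # g/mol of the simulation box
    box_volume: float  # Angstrom^3
    inaccessible: bool
    config: GCMCConfig
    final_n: int = 0
    energy_drift: float = 0.0  # |incremental - recomputed| relative, end of run


def _uniform_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Shoemake's uniform random rotation matrix."""
    u1, u2, u3 = rng.random(3)
    q = np.array([
        math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
        math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
        math.sqrt(u1) * math.sin(2 * math.pi * u3),
        math.sqrt(u1) * math.cos(2 * math.pi * u3),
    ])
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class _System:
    """Precomputed interaction tables for one framework/guest/force-field trio."""

    def __init__(self, structure: PeriodicStructure, guest: RigidGuest, ff: ForceField):
        self.cell = structure.cell
        self.matrix = structure.cell.matrix
        self.inv_matrix = np.linalg.inv(self.matrix)
        self.fw_frac = structure.frac_coords
        self.ff = ff
        self.rc2 = ff.cutoff ** 2
        self.guest = guest
        self.site_types = guest.site_types
        self.type_index = {t: k for k, t in enumerate(dict.fromkeys(self.site_types))}
        self.site_type_codes = np.array([self.type_index[t] for t in self.site_types])
        # guest-site-type vs framework-atom tables
        n_types = len(self.type_index)
        n_fw = len(self.fw_frac)
        self.fw_eps = np.zeros((n_types, n_fw))
        self.fw_sig2 = np.zeros((n_types, n_fw))
        fw_elements = structure.elements
        for t, k in self.type_index.items():
            for a, el in enumerate(fw_elements):
                eps, sig = ff.mixed(t, el)
                self.fw_eps[k, a] = eps
                self.fw_sig2[k, a] = sig * sig
        # guest-site-type vs guest-site-type tables
        self.gg_eps = np.zeros((n_types, n_types))
        self.gg_sig2 = np.zeros((n_types, n_types))
        for ti, ki in self.type_index.items():
            for tj, kj in self.type_index.items():
                eps, sig = ff.mixed(ti, tj)
                self.gg_eps[ki, kj] = eps
                self.gg_sig2[ki, kj] = sig * sig
        if ff.shifted:
            self.fw_shift = self._lj(self.fw_eps, self.fw_sig2, np.full_like(self.fw_eps, self.rc2), shift=False)
            self.gg_shift = self._lj(self.gg_eps, self.gg_sig2, np.full_like(self.gg_eps, self.rc2), shift=False)
        else:
            self.fw_shift = None
            self.gg_shift = None

    @staticmethod
    def _lj(eps, sig2, r2, shift=False):
        x6 = (sig2 / r2) ** 3
        return 4.0 * eps * (x6 * x6 - x6)

    def _min_image_vecs(self, frac_from: np.ndarray, frac_to: np.ndarray) -> np.ndarray:
        d = frac_to - frac_from
        d -= np.round(d)
        return d @ self.matrix

    def site_positions(self, center_cart: np.ndarray, rot: np.ndarray) -> np.ndarray:
        return center_cart + self.guest.body_coords @ rot.T

    def framework_energy(self, site_carts: np.ndarray) -> float:
        """Guest-framework energy of one guest (K); +inf on overlap."""
        total = 0.0
        frac = site_carts @ self.inv_matrix
        for s in range(len(site_carts)):
            k = self.site_type_codes[s]
            vecs = self._min_image_vecs(frac[s], self.fw_frac)
            r2 = np.einsum("ij,ij->i", vecs, vecs)
            within = r2 < self.rc2
            if not within.any():
                continue
            r2w = r2[within]
            if (r2w < 1e-8).any():
                return math.inf
            u = self._lj(self.fw_eps[k, within], self.fw_sig2[k, within], r2w)
            if self.fw_shift is not None:
                u = u - self.fw_shift[k, within]
            total += float(u.sum())
        return total

    def guest_guest_energy(
        self, site_carts: np.ndarray, other_carts: np.ndarray, other_codes: np.ndarray
    ) -> float:
        """Energy of one guest against a flat array of other guests' sites (K)."""
        if len(other_carts) == 0:
            return 0.0
        total = 0.0
        frac = site_carts @ self.inv_matrix
        other_frac = other_carts @ self.inv_matrix
        for s in range(len(site_carts)):
            k = self.site_type_codes[s]
            vecs = self._min_image_vecs(frac[s], other_frac)
            r2 = np.einsum("ij,ij->i", vecs, vecs)
            within = r2 < self.rc2
            if not within.any():
                continue
            r2w = r2[within]
            if (r2w < 1e-8).any():
                return math.inf
            codes = other_codes[within]
            u = self._lj(self.gg_eps[k, codes], self.gg_sig2[k, codes], r2w)
            if self.gg_shift is not None:
                u = u - self.gg_shift[k, codes]
            total += float(u.sum())
        return total


class _State:
    def __init__(self, system: _System):
        self.system = system
        self.guests: list[np.ndarray] = []  # site cartesian positions per guest
        self.energy = 0.0

    @property
    def n(self) -> int:
        return len(self.guests)

    def flat_sites(self, exclude: int | None = None):
        arrs = [g for k, g in enumerate(self.guests) if k != exclude]
        if not arrs:
            s = len(self.system.site_types)
            return np.empty((0, 3)), np.empty(0, dtype=int)
        carts = np.vstack(arrs)
        codes = np.tile(self.system.site_type_codes, len(arrs))
        return carts, codes

    def guest_energy(self, site_carts: np.ndarray, exclude: int | None = None) -> float:
        u_fw = self.system.framework_energy(site_carts)
        if not math.isfinite(u_fw):
            return math.inf
        others, codes = self.flat_sites(exclude)
        u_gg = self.system.guest_guest_energy(site_carts, others, codes)
        return u_fw + u_gg

    def total_energy(self) -> float:
        """Full recomputation (pairwise counted once) for drift checks."""
        total = 0.0
        for k, g in enumerate(self.guests):
            total += self.system.framework_energy(g)
            for j in range(k + 1, self.n):
                total += self.system.guest_guest_energy(
                    g, self.guests[j], self.system.site_type_codes
                )
        return total


def run_gcmc(
    structure: PeriodicStructure,
    guest: RigidGuest,
    ff: ForceField,
    config: GCMCConfig,
    insert_filter=None,
) -> GCMCResult:
    """Single-component GCMC in the rigid framework at fixed T and fugacity.

    ``insert_filter(frac_center) -> bool`` optionally rejects insertions and
    displacements whose center lands outside the accessible (percolating)
    pore network, emulating pocket blocking.
    """
    supercell = build_supercell(
        structure, max(2 * ff.cutoff, config.min_box_width)
    ) if structure.n_sites else structure
    system = _System(supercell, guest, ff)
    state = _State(system)
    rng = np.random.default_rng(config.seed)

    volume_m3 = supercell.cell.volume * 1e-30
    bfv = config.fugacity * volume_m3 / (BOLTZMANN_J_PER_K * config.temperature)
    beta = 1.0 / config.temperature  # energies in K

    p_insert, p_delete, p_translate, p_rotate = config.move_probabilities
    edges = np.cumsum([p_insert, p_delete, p_translate, p_rotate])
    delta = config.max_translation
    attempts = {"insert": 0, "delete": 0, "translate": 0, "rotate": 0}
    accepts = dict.fromkeys(attempts, 0)
    insertion_ever_accepted = False

    def do_step(tune: bool):
        nonlocal delta, insertion_ever_accepted
        u = rng.random()
        if u < edges[0]:
            kind = "insert"
            frac_center = rng.random(3)
            if insert_filter is not None and not insert_filter(frac_center):
                attempts[kind] += 1
                return
            center = frac_center @ system.matrix
            rot = _uniform_quaternion(rng)
            sites = system.site_positions(center, rot)
            du = state.guest_energy(sites)
            attempts[kind] += 1
            if math.isfinite(du) and rng.random() < min(
                1.0, bfv / (state.n + 1) * math.exp(-beta * du)
            ):
                state.guests.append(sites)
                state.energy += du
                accepts[kind] += 1
                insertion_ever_accepted = True
        elif u < edges[1]:
            kind = "delete"
            attempts[kind] += 1
            if state.n == 0:
                return
            g = int(rng.integers(state.n))
            du = -state.guest_energy(state.guests[g], exclude=g)
            if rng.random() < min(1.0, state.n / bfv * math.exp(-beta * du)):
                state.energy += du
                state.guests.pop(g)
                accepts[kind] += 1
        else:
            rotate = u >= edges[2]
            kind = "rotate" if rotate else "translate"
            attempts[kind] += 1
            if state.n == 0:
                return
            g = int(rng.integers(state.n))
            old = state.guests[g]
            centroid = old.mean(axis=0)
            if rotate:
                rot = _uniform_quaternion(rng)
                new = system.site_positions(centroid, rot)
            else:
                disp = (rng.random(3) - 0.5) * 2 * delta
                new_centroid = centroid + disp
                frac_c = (new_centroid @ system.inv_matrix) % 1.0
                if insert_filter is not None and not insert_filter(frac_c):
                    return
                new_centroid = frac_c @ system.matrix
                new = old + (new_centroid - centroid)
            u_old = state.guest_energy(old, exclude=g)
            u_new = state.guest_energy(new, exclude=g)
            du = u_new - u_old
            if math.isfinite(du) and rng.random() < min(1.0, math.exp(-beta * du)):
                state.guests[g] = new
                state.energy += du
                accepts[kind] += 1
        if tune and attempts["translate"] > 0 and attempts["translate"] % 500 == 0:
            rate = accepts["translate"] / attempts["translate"]
            if rate > 0.45:
                delta = min(delta * 1.1, float(min(supercell.cell.perpendicular_widths)) / 4)
            elif rate < 0.35:
                delta = max(delta * 0.9, 0.05)

    for _ in range(config.equilibration):
        do_step(tune=True)
    # freeze delta; reset counters for production statistics
    attempts = dict.fromkeys(attempts, 0)
    accepts = dict.fromkeys(accepts, 0)

    n_trace = np.empty(config.cycles)
    e_trace = np.empty(config.cycles)
    for step in range(config.cycles):
        do_step(tune=False)
        n_trace[step] = state.n
        e_trace[step] = state.energy

    blocks = np.array_split(n_trace, config.n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    mean_n = float(block_means.mean())
    se = float(block_means.std(ddof=1) / math.sqrt(len(block_means)))

    recomputed = state.total_energy()
    denom = max(abs(recomputed), 1.0)
    drift = abs(state.energy - recomputed) / denom

    mass_box = supercell.mass_per_cell
    if mass_box > 0:
        mg_g, wt = loading_conversions(mean_n, guest.molar_mass, mass_box)
    else:  # atom-free test boxes: loading per gram is undefined
        mg_g, wt = 0.0, 0.0
    rates = {
        k: (accepts[k] / attempts[k] if attempts[k] else 0.0) for k in attempts
    }
    inaccessible = (not insertion_ever_accepted) and attempts["insert"] + config.equilibration > 0 and state.n == 0 and mean_n == 0.0
    return GCMCResult(
        mean_n=mean_n,
        mean_n_se=se,
        var_n=float(n_trace.var()),
        loading_mg_per_g=mg_g,
        loading_wt_percent=wt,
        acceptance_rates=rates,
        mean_energy=float(e_trace.mean()),
        framework_mass_box=mass_box,
        box_volume=supercell.cell.volume,
        inaccessible=inaccessible,
        config=config,
        final_n=state.n,
        energy_drift=float(drift),
    )


def widom_henry(
    structure: PeriodicStructure,
    guest: RigidGuest,
    ff: ForceField,
    temperature: float,
    insertions: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Henry coefficient by Widom test-particle insertion.

    K_H = beta <exp(-beta dU)> over uniform random positions/orientations.
    Returns (K_H in molecules A^-3 Pa^-1, MC standard error).  For an empty
    box K_H = 1/(k_B T): 2.4146e20 m^-3 Pa^-1 at 300 K.
    """
    if insertions < 10**4:
        raise ValueError("need at least 1e4 insertions for a stable Widom estimate")
    supercell = build_supercell(structure, 2 * ff.cutoff) if structure.n_sites else structure
    system = _System(supercell, guest, ff)
    rng = np.random.default_rng(seed)
    beta = 1.0 / temperature
    boltz = np.empty(insertions)
    for t in range(insertions):
        center = rng.random(3) @ system.matrix
        rot = _uniform_quaternion(rng)
        du = system.framework_energy(system.site_positions(center, rot))
        boltz[t] = 0.0 if not math.isfinite(du) else math.exp(-beta * du)
    mean = float(boltz.mean())
    se_mean = float(boltz.std(ddof=1) / math.sqrt(insertions))
    conv = 1.0 / (BOLTZMANN_J_PER_K * temperature) * 1e-30  # molecules A^-3 Pa^-1
    return mean * conv, se_mean * conv


def lattice_isotherm(n_sites: int, beta_eps: float, z: float) -> float:
    """Closed-form mean occupancy of independent sites: M x/(1+x), x = z e^(-beta eps)."""
    x = z * math.exp(-beta_eps)
    return n_sites * x / (1.0 + x)


def run_lattice_gcmc(
    n_sites: int,
    beta_eps: float,
    z: float,
    steps: int = 20000,
    equilibration: int = 2000,
    seed: int = 0,
    n_blocks: int = 10,
) -> tuple[float, float]:
    """GCMC on independent adsorption sites (activity z, site energy eps).

    Exact stationary distribution is the Langmuir isotherm, making this an
    analytic oracle for the acceptance-rule implementation.  Returns
    (mean N, block standard error).
    """
    rng = np.random.default_rng(seed)
    occupied = np.zeros(n_sites, dtype=bool)
    x = z * math.exp(-beta_eps)
    n = 0
    trace = np.empty(steps)
    for t in range(-equilibration, steps):
        site = int(rng.integers(n_sites))
        if rng.random() < 0.5:  # insertion attempt
            if not occupied[site] and rng.random() < min(1.0, x):
                occupied[site] = True
                n += 1
        else:  # deletion attempt
            if occupied[site] and rng.random() < min(1.0, 1.0 / x):
                occupied[site] = False
                n -= 1
        if t >= 0:
            trace[t] = n
    blocks = np.array_split(trace, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(n_blocks))


def loading_conversions(
    mean_n: float, guest_molar_mass: float, framework_mass_box: float
) -> tuple[float, float]:
    """Convert mean guest count per box to (mg drug / g MOF, wt.% of total).

    1000 mg/g corresponds to 50 wt.% under the total-mass convention.
    """
    if framework_mass_box <= 0:
        raise ValueError("framework mass must be positive")
    mg_per_g = 1000.0 * mean_n * guest_molar_mass / framework_mass_box
    wt_percent = 100.0 * mg_per_g / (1000.0 + mg_per_g)
    return mg_per_g, wt_percent
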