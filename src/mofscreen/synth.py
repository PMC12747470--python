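"""Synthetic inputs for every pipeline stage.

Licensed structure databases cannot be redistributed, so the package ships
generators for every input the screening cascade needs: toy frameworks
with closed-form pore metrics, lattice-gas systems with exact isotherms,
coarse rigid guest models spanning the three chemotherapeutic size
classes, linker-toxicity datasets with planted fragment rules and a
computable Bayes accuracy, and a mixed six-framework screening library
with a ground-truth manifest.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import norm

from .elements import vdw_radius
from .gcmc import ForceField, RigidGuest, lattice_isotherm
from .molecules import from_smiles
from .structures import AtomSite, PeriodicStructure, SmallMolecule, UnitCell
from .toxicity import (
    CategoryThresholds,
    ToxicityCategory,
    ToxicityDataset,
    ld50_to_custom_category,
)

__all__ = [
    "DEFAULT_FORCE_FIELD",
    "make_cubic_framework",
    "make_dense_block",
    "make_channel_framework",
    "synthetic_pcn222_channel_model",
    "make_dilation_series",
    "LatticeGasSystem",
    "make_lattice_gas",
    "make_guest_models",
    "SyntheticToxicitySpec",
    "make_toxicity_dataset",
    "make_screening_library",
    "corner_lattice_lcd",
    "corner_lattice_pld",
]


def _default_ff_params() -> dict[str, tuple[float, float]]:
    # UFF-style LJ well depths (K) and diameters (A) for framework elements,
    # TraPPE-style single-site parameters for the coarse guest beads.
    return {
        "H": (22.14, 2.571),
        "C": (52.84, 3.431),
        "N": (34.72, 3.261),
        "O": (30.19, 3.118),
        "F": (25.16, 2.997),
        "S": (137.88, 3.595),
        "Cl": (114.23, 3.516),
        "Br": (126.30, 3.732),
        "Zn": (62.40, 2.462),
        "Zr": (34.72, 2.783),
        "Cd": (114.73, 2.537),
        "Ni": (7.55, 2.525),
        "Fe": (6.54, 2.594),
        "Cu": (2.52, 3.114),
        "Ti": (8.56, 2.829),
        # coarse guest beads (one per drug size class) and test probes
        "gem_bead": (300.0, 5.2),
        "sn38_bead": (280.0, 4.6),
        "pac_bead": (260.0, 4.8),
        "lj_sphere": (148.0, 3.73),
        "ideal_sphere": (0.0, 1.0),
    }


DEFAULT_FORCE_FIELD = ForceField(params=_default_ff_params())


# ---------------------------------------------------------------------------
# Toy frameworks with closed-form pore metrics
# ---------------------------------------------------------------------------


def corner_lattice_lcd(a: float, r: float) -> float:
    """Closed form: body-center inscribed sphere of a corner-atom cubic lattice."""
    return math.sqrt(3.0) * a - 2.0 * r


def corner_lattice_pld(a: float, r: float) -> float:
    """Closed form: face-center bottleneck of a corner-atom cubic lattice."""
    return math.sqrt(2.0) * a - 2.0 * r


def make_cubic_framework(a: float, element: str = "C", name: str | None = None) -> PeriodicStructure:
    """Cubic cell with one atom at the corner.

    Closed forms hold: LCD = sqrt(3) a - 2r, PLD = sqrt(2) a - 2r for vdW
    radius r.  Porous only when a exceeds roughly twice the atom diameter.
    """
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    cell = UnitCell(a, a, a)
    sites = [AtomSite(element=element, frac=(0.0, 0.0, 0.0))]
    return PeriodicStructure(cell=cell, sites=sites, name=name or f"cubic_{element}_{a:g}")


def make_dense_block(a: float = 4.5, element: str = "Zr", name: str | None = None) -> PeriodicStructure:
    """A corner-atom cell too tight for any drug-sized guest to percolate."""
    return make_cubic_framework(a, element, name or f"dense_{element}_{a:g}")


def make_channel_framework(
    lengths: tuple[float, float, float],
    channels: list[tuple[float, float, float]],
    element: str = "C",
    wall_spacing: float = 2.0,
    name: str = "channel_framework",
) -> PeriodicStructure:
    """Orthorhombic framework with straight 1D channels along the c axis.

    ``channels`` lists (frac_x, frac_y, diameter A).  Wall atoms fill the
    non-channel region on a cubic grid; atoms bordering a channel are
    snapped radially onto the channel surface so the realized free diameter
    equals the requested one to within the pore-grid resolution.
    """
    la, lb, lc = lengths
    cell = UnitCell(la, lb, lc)
    r_atom = vdw_radius(element)
    # exclusion radius: atom centers must keep their vdW surface off the channel
    excl = [(cx * la, cy * lb, d / 2 + r_atom) for cx, cy, d in channels]

    def radial(x, y, cx, cy):
        dx = x - cx
        dx -= round(dx / la) * la
        dy = y - cy
        dy -= round(dy / lb) * lb
        return math.hypot(dx, dy), dx, dy

    nx, ny, nz = (max(1, round(l / wall_spacing)) for l in lengths)
    sites: list[AtomSite] = []
    for ix in range(nx):
        for iy in range(ny):
            x, y = ix * la / nx, iy * lb / ny
            dists = [radial(x, y, cx, cy) for cx, cy, _ in excl]
            if any(r < R - 1e-9 for (r, _, _), (_, _, R) in zip(dists, excl)):
                continue
            # snap near-boundary atoms exactly onto the nearest channel surface
            gaps = [r - R for (r, _, _), (_, _, R) in zip(dists, excl)]
            k = int(np.argmin(gaps))
            xs, ys = x, y
            if gaps[k] < wall_spacing:
                (r, dx, dy), (cx, cy, R) = dists[k], excl[k]
                if r > 1e-9:
                    scale = R / r
                    xs, ys = cx + dx * scale, cy + dy * scale
                    ok = all(
                        radial(xs, ys, c2x, c2y)[0] >= R2 - 1e-9
                        for j, (c2x, c2y, R2) in enumerate(excl)
                        if j != k
                    )
                    if not ok:
                        xs, ys = x, y
            for iz in range(nz):
                z = iz * lc / nz
                sites.append(
                    AtomSite(element=element, frac=(xs / la % 1.0, ys / lb % 1.0, z / lc))
                )
    return PeriodicStructure(cell=cell, sites=sites, name=name)


def synthetic_pcn222_channel_model() -> PeriodicStructure:
    """Synthetic geometric stand-in for the PCN-222 channel system.

    PCN-222 (Zr6 clusters bridged by tetrakis(4-carboxyphenyl)porphyrin)
    carries two 1D channel systems: mesoporous hexagonal channels of about
    3.6 nm and triangular microchannels of about 1.7 nm diameter.  The real
    crystal structure is licensed and not redistributable, so this is a
    coarse-grained SYNTHETIC stand-in: an orthorhombic cell with straight
    cylindrical channels of exactly those two free diameters, walls of
    carbon-like atoms.  It reproduces the channel-size fingerprint (LCD,
    PSD peaks), not the crystallography.
    """
    return make_channel_framework(
        lengths=(46.0, 46.0, 12.0),
        channels=[(0.0, 0.0, 36.0), (0.5, 0.5, 17.0)],
        element="C",
        wall_spacing=2.0,
        name="synthetic_pcn222_channel_model",
    )


def make_dilation_series(
    base_a: float = 16.0, factors: tuple[float, ...] = (1.0, 1.2, 1.5, 2.0),
    element: str = "C",
) -> list[PeriodicStructure]:
    """Uniformly dilated copies of the corner-atom topology.

    Accessible pore volume is strictly increasing in the factor, which makes
    the family the fixture for the loading-vs-pore-volume scaling claim.
    """
    if any(f < 1 for f in factors):
        raise ValueError("dilation factors must be >= 1")
    return [
        make_cubic_framework(base_a * f, element, name=f"dilation_{f:g}") for f in factors
    ]


# ---------------------------------------------------------------------------
# Lattice gas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeGasSystem:
    """Independent adsorption sites with a closed-form Langmuir isotherm."""

    n_sites: int
    beta_eps: float  # site energy in units of k_B T

    def mean_occupancy(self, z: float) -> float:
        return lattice_isotherm(self.n_sites, self.beta_eps, z)


def make_lattice_gas(n_sites: int = 100, beta_eps: float = 0.0) -> LatticeGasSystem:
    if n_sites < 1:
        raise ValueError("need at least one site")
    return LatticeGasSystem(n_sites=n_sites, beta_eps=beta_eps)


# ---------------------------------------------------------------------------
# Guest models
# ---------------------------------------------------------------------------


def make_guest_models() -> dict[str, RigidGuest]:
    """Coarse rigid guests for the three drug size classes plus test probes.

    Molar masses are the exact formula masses of gemcitabine (C9H11F2N3O4,
    263.2 g/mol), SN-38 (C22H20N2O5, 392.4 g/mol), and paclitaxel
    (C47H51NO14, 853.9 g/mol); site counts and spreads grow with drug bulk
    so the minimal projection diameters are strictly ordered.
    """
    s = 6.0 / math.sqrt(8.0 / 3.0)  # tetrahedron circumradius for edge 6 A
    guests = {
        "gemcitabine_like": RigidGuest(
            name="gemcitabine_like",
            sites=[("gem_bead", (0.0, 0.0, 0.0), 0.0)],
            molar_mass=263.2,
        ),
        "sn38_like": RigidGuest(
            name="sn38_like",
            sites=[
                ("sn38_bead", (0.0, 0.0, 0.0), 0.0),
                ("sn38_bead", (4.0, 0.0, 0.0), 0.0),
                ("sn38_bead", (2.0, 3.464, 0.0), 0.0),
            ],
            molar_mass=392.4,
        ),
        "paclitaxel_like": RigidGuest(
            name="paclitaxel_like",
            sites=[
                ("pac_bead", (0.0, 0.0, 0.0), 0.0),
                ("pac_bead", (s, s, s), 0.0),
                ("pac_bead", (s, -s, -s), 0.0),
                ("pac_bead", (-s, s, -s), 0.0),
                ("pac_bead", (-s, -s, s), 0.0),
            ],
            molar_mass=853.9,
        ),
        "lj_sphere": RigidGuest(
            name="lj_sphere", sites=[("lj_sphere", (0.0, 0.0, 0.0), 0.0)], molar_mass=16.04
        ),
        "ideal_sphere": RigidGuest(
            name="ideal_sphere",
            sites=[("ideal_sphere", (0.0, 0.0, 0.0), 0.0)],
            molar_mass=1.0,
        ),
    }
    return guests


# ---------------------------------------------------------------------------
# Toxicity dataset with planted rules
# ---------------------------------------------------------------------------

#: Multiplicative LD50 effect of each planted fragment (relative to base).
FRAGMENT_EFFECTS: dict[str, float] = {
    "nitro": 0.05,
    "cyano": 0.04,
    "halide": 0.55,
    "amine": 0.30,
    "carboxyl": 1.15,
    "methyl": 1.05,
    "hydroxyl": 1.10,
}

_FRAGMENT_SMILES: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "cyano": "C#N",
    "halide": "Cl",
    "amine": "N",
    "carboxyl": "C(=O)O",
    "methyl": "C",
    "hydroxyl": "O",
}

#: Baseline LD50 (mg/kg) of an undecorated scaffold.
BASE_LD50 = 8000.0

_MILD = ["carboxyl", "methyl", "hydroxyl"]

# ring templates by substituent count; validated against RDKit in the tests
_TEMPLATES: dict[str, dict[int, str]] = {
    "benzene": {
        1: "c1ccc({0})cc1",
        2: "c1ccc({0})cc1{1}",
        3: "c1cc({0})cc({1})c1{2}",
        4: "c1c({0})cc({1})c({2})c1{3}",
    },
    "pyridine": {
        1: "c1ccc({0})nc1",
        2: "c1ccc({0})nc1{1}",
        3: "c1cc({0})nc({1})c1{2}",
    },
}


def _assemble_smiles(scaffold: str, fragments: list[str]) -> tuple[str, list[str]]:
    """Build a SMILES from scaffold + fragments; returns the fragments kept
    (overflow decorations beyond the scaffold's slots are dropped)."""
    templates = _TEMPLATES[scaffold]
    k = len(fragments)
    while k not in templates and k > 0:
        k -= 1
    if k == 0:
        return ("c1ccccc1" if scaffold == "benzene" else "c1ccncc1"), []
    used = fragments[:k]
    return templates[k].format(*[_FRAGMENT_SMILES[f] for f in used]), used


@dataclass(frozen=True)
class SyntheticToxicitySpec:
    """Parameters of the category-conditional linker-toxicity generator."""

    n: int = 2000
    priors: tuple[float, float, float] = (0.25, 0.35, 0.40)  # fatal, toxic, safe
    noise_sigma: float = 0.35  # lognormal sigma in log10 units
    seed: int = 7
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)

    def __post_init__(self):
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if self.n < 1 or self.noise_sigma <= 0:
            raise ValueError("invalid generator spec")


def _draw_fragments(category: ToxicityCategory, rng: np.random.Generator) -> list[str]:
    mild = list(rng.choice(_MILD, size=rng.integers(0, 3), replace=True))
    if category == ToxicityCategory.fatal:
        return ["nitro", "cyano", "halide"] + mild[:1]
    if category == ToxicityCategory.toxic:
        strong = [str(rng.choice(["nitro", "cyano"]))]
        return strong + mild[:2]
    return mild if mild else [str(rng.choice(_MILD))]


def _center_ld50(fragments: list[str]) -> float:
    c = BASE_LD50
    for f in fragments:
        c *= FRAGMENT_EFFECTS[f]
    return c


def _bayes_prediction(center: float, sigma: float, thresholds: CategoryThresholds):
    """Most probable category of log-normal LD50 noise around a known center."""
    lo, hi = math.log10(thresholds.fatal), math.log10(thresholds.safe)
    mu = math.log10(center)
    p_fatal = norm.cdf((lo - mu) / sigma)
    p_safe = 1.0 - norm.cdf((hi - mu) / sigma)
    p_toxic = 1.0 - p_fatal - p_safe
    probs = [p_fatal, p_toxic, p_safe]
    return ToxicityCategory(int(np.argmax(probs)))


def make_toxicity_dataset(spec: SyntheticToxicitySpec = SyntheticToxicitySpec()) -> ToxicityDataset:
    """Generate a linker-toxicity dataset with planted fragment rules.

    Molecules are benzene/pyridine scaffolds decorated from a small fragment
    grammar; each fragment multiplies the LD50 center (e.g. a nitro group
    multiplies it by 0.05); realized LD50 is log-normal around the center
    and the label follows from the three-class thresholds.  The realized
    accuracy of the Bayes-optimal rule (which knows the planted centers) is
    attached; under default noise it exceeds 0.90.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    bayes_hits = 0
    for _ in range(spec.n):
        intended = ToxicityCategory(int(rng.choice(3, p=spec.priors)))
        fragments = _draw_fragments(intended, rng)
        scaffold = str(rng.choice(["benzene", "pyridine"], p=[0.7, 0.3]))
        smiles, used = _assemble_smiles(scaffold, fragments)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # malformed template combination: fall back to benzene
            smiles, used = _assemble_smiles("benzene", fragments)
            mol = Chem.MolFromSmiles(smiles)
        smiles = Chem.MolToSmiles(mol)
        center = _center_ld50(used)
        ld50 = center * 10.0 ** (spec.noise_sigma * rng.standard_normal())
        label = ld50_to_custom_category(ld50, spec.thresholds)
        bayes_label = _bayes_prediction(center, spec.noise_sigma, spec.thresholds)
        if bayes_label == label:
            bayes_hits += 1
        rows.append(
            {
                "smiles": smiles,
                "ld50_mg_per_kg": ld50,
                "label": label,
                "ld50_center": center,
                "bayes_label": bayes_label,
            }
        )
    frame = pd.DataFrame(rows)
    return ToxicityDataset(
        frame=frame,
        provenance=f"synthetic(n={spec.n}, seed={spec.seed}, sigma={spec.noise_sigma})",
        thresholds=spec.thresholds,
        bayes_accuracy=bayes_hits / spec.n,
    )


# ---------------------------------------------------------------------------
# Screening library with ground-truth manifest
# ---------------------------------------------------------------------------

_BDC_SMILES = "OC(=O)c1ccc(cc1)C(=O)O"  # terephthalic acid (protonated BDC)


def _place_fragment(
    structure: PeriodicStructure, molecule: SmallMolecule, frac_center: tuple[float, float, float]
) -> PeriodicStructure:
    """Insert a finite molecule's atoms into the cell around a fractional point."""
    coords = molecule.coords - molecule.coords.mean(axis=0)
    center = structure.cell.frac_to_cart(np.asarray(frac_center))
    inv = np.linalg.inv(structure.cell.matrix)
    sites = list(structure.sites)
    for el, xyz in zip(molecule.elements, coords + center):
        frac = (xyz @ inv) % 1.0
        sites.append(AtomSite(element=el, frac=tuple(frac)))
    return PeriodicStructure(cell=structure.cell, sites=sites, name=structure.name)


def make_screening_library(seed: int = 0):
    """The six-framework end-to-end fixture with a ground-truth manifest.

    Two frameworks carry toxic metal nodes (Cd, Ni) and must fail
    biocompatibility; two are dense Zr blocks and must fail the porosity
    gate; two are porous Zr frameworks with a safe terephthalate-type
    linker and must reach the loading stage.  Stage survivor counts along
    the cascade are 6 -> 4 -> 2 by construction.
    """
    bdc = from_smiles(_BDC_SMILES)
    structures = []
    manifest = {}

    for metal, name in (("Cd", "Cd_bdc_toxic_metal"), ("Ni", "Ni_bdc_toxic_metal")):
        s = make_cubic_framework(25.0, metal, name=name)
        s = _place_fragment(s, bdc, (0.25, 0.25, 0.25))
        structures.append(s)
        manifest[name] = {"expected_stage": "biocompat", "reason": f"metal:{metal}"}

    for a, name in ((4.5, "Zr_dense_a45"), (5.0, "Zr_dense_a50")):
        structures.append(make_dense_block(a, "Zr", name=name))
        manifest[name] = {"expected_stage": "porosity", "reason": "pld below guest diameter"}

    for a, name in ((25.0, "Zr_bdc_porous_a25"), (30.0, "Zr_bdc_porous_a30")):
        s = make_cubic_framework(a, "Zr", name=name)
        s = _place_fragment(s, bdc, (0.25, 0.25, 0.25))
        structures.append(s)
        manifest[name] = {"expected_stage": "loading", "reason": "porous and biocompatible"}

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(structures))
    structures = [structures[i] for i in order]
    return structures, manifest
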