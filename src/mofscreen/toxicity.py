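"""Biocompatibility prediction for MOF building blocks.

Metal centers are judged against a curated acute-toxicity table; organic
linkers are classified into three ordered categories — fatal < toxic < safe
— by a tree-ensemble model trained on molecules labelled with oral-rat LD50
(mg per kg body weight).  The three categories are a coarsening of the UN
GHS acute-oral scheme: the GHS bins chemicals into Categories 1-5 by LD50,
and the custom scheme groups Cat 1-2 as "fatal", Cat 3-4 as "toxic", and
Cat 5 / not-classified as "safe" (thresholds configurable).

A MOF is "highly biocompatible" only if every metal element is
biocompatible in the table AND every unique linker is predicted safe; an
explicit whitelist can admit metals (e.g. Fe, Zn) on experimental evidence.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .deconstruct import BuildingBlocks
from .molecules import ensure_coords, to_rdkit
from .structures import SmallMolecule

__all__ = [
    "ToxicityCategory",
    "GhsCategory",
    "CategoryThresholds",
    "ld50_to_ghs_category",
    "ld50_to_custom_category",
    "assign_partial_charges",
    "LinkerFeatures",
    "featurize_linker",
    "FEATURE_VERSION",
    "ToxicityDataset",
    "ToxicityClassifier",
    "train_toxicity_classifier",
    "TrainingReport",
    "predict_toxicity",
    "load_metal_table",
    "MetalToxicityRecord",
    "assess_mof_biocompatibility",
    "BiocompatibilityReport",
    "UnknownMetalError",
]


class ToxicityCategory(enum.IntEnum):
    """Three-class linker verdict, totally ordered fatal < toxic < safe."""

    fatal = 0
    toxic = 1
    safe = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class GhsCategory(enum.Enum):
    Cat1 = "Cat1"
    Cat2 = "Cat2"
    Cat3 = "Cat3"
    Cat4 = "Cat4"
    Cat5 = "Cat5"
    NotClassified = "NotClassified"


# UN GHS acute-oral bin upper bounds (mg/kg), inclusive.
_GHS_BINS = [
    (5.0, GhsCategory.Cat1),
    (50.0, GhsCategory.Cat2),
    (300.0, GhsCategory.Cat3),
    (2000.0, GhsCategory.Cat4),
    (5000.0, GhsCategory.Cat5),
]


def ld50_to_ghs_category(ld50: float) -> GhsCategory:
    """Map an oral-rat LD50 (mg/kg) to its UN GHS acute-oral category."""
    if ld50 <= 0:
        raise ValueError("LD50 must be positive")
    for bound, cat in _GHS_BINS:
        if ld50 <= bound:
            return cat
    return GhsCategory.NotClassified


@dataclass(frozen=True)
class CategoryThresholds:
    """LD50 cut points (mg/kg) of the three-class scheme, upper bounds inclusive."""

    fatal: float = 50.0
    safe: float = 2000.0

    def __post_init__(self):
        if not 0 < self.fatal < self.safe:
            raise ValueError("thresholds must satisfy 0 < fatal < safe")


def ld50_to_custom_category(
    ld50: float, thresholds: CategoryThresholds = CategoryThresholds()
) -> ToxicityCategory:
    """Three-class category: fatal (<= t_fatal), toxic, or safe (> t_safe)."""
    if ld50 <= 0:
        raise ValueError("LD50 must be positive")
    if ld50 <= thresholds.fatal:
        return ToxicityCategory.fatal
    if ld50 <= thresholds.safe:
        return ToxicityCategory.toxic
    return ToxicityCategory.safe


# ---------------------------------------------------------------------------
# Partial charges
# ---------------------------------------------------------------------------


def assign_partial_charges(molecule: SmallMolecule, n_iter: int = 8) -> SmallMolecule:
    """Assign Gasteiger-Marsili partial charges (iterative PEOE).

    Returns a copy whose per-atom charges sum to the net formal charge
    within 1e-6 e.
    """
    mol = to_rdkit(molecule)
    AllChem.ComputeGasteigerCharges(mol, nIter=n_iter, throwOnParamFailure=False)
    charges = []
    for atom in mol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(q):
            q = 0.0
        charges.append(q)
    charges = np.asarray(charges)
    if molecule.n_atoms != len(charges):
        raise RuntimeError("atom count changed during charge assignment")
    # renormalize tiny numeric drift onto all atoms so the sum is exact
    drift = (molecule.net_charge - charges.sum()) / max(len(charges), 1)
    charges = charges + drift
    atoms = [
        (el, xyz, float(q))
        for (el, xyz, _), q in zip(molecule.atoms, charges)
    ]
    return SmallMolecule(
        atoms=atoms,
        bonds=list(molecule.bonds),
        net_charge=molecule.net_charge,
        notation=molecule.notation,
    )


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

FEATURE_VERSION = "1"

#: Versioned substructure-pattern list (name, SMARTS).
FRAGMENT_SMARTS: list[tuple[str, str]] = [
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("carboxylate", "[CX3](=O)[O-]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("amide", "[CX3](=O)[NX3]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("nitro", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("azide", "[NX2]=[NX2+]=[NX1-]"),
    ("azo", "[#6][NX2]=[NX2][#6]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("aromatic_amine", "[NX3;H2,H1;!$(NC=O)]c"),
    ("aliphatic_amine", "[NX3;H2,H1;!$(NC=O)][CX4]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]"),
    ("hydroxyl_aliphatic", "[OX2H][CX4]"),
    ("phenol", "[OX2H]c"),
    ("ether", "[OD2]([#6])[#6]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("sulfonic_acid", "[SX4](=O)(=O)[OX2H,OX1-]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("phosphate", "[PX4](=O)([OX2H,OX1-,OX2])([OX2H,OX1-,OX2])"),
    ("fluoride", "[F]"),
    ("chloride", "[Cl]"),
    ("bromide", "[Br]"),
    ("iodide", "[I]"),
    ("trifluoromethyl", "[CX4]([F])([F])[F]"),
    ("benzene_ring", "c1ccccc1"),
    ("pyridine_ring", "n1ccccc1"),
    ("pyrimidine_ring", "c1cncnc1"),
    ("imidazole_ring", "c1cnc[nH]1"),
    ("pyrrole_ring", "c1cc[nH]c1"),
    ("furan_ring", "c1ccoc1"),
    ("thiophene_ring", "c1ccsc1"),
    ("triazole_ring", "c1nnc[nH0,nH]1"),
    ("tetrazole_ring", "c1nnn[nH0,nH]1"),
    ("epoxide", "C1OC1"),
    ("aziridine", "C1NC1"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("methyl", "[CH3]"),
    ("quaternary_ammonium", "[NX4+]"),
    ("hydrazine", "[NX3][NX3]"),
    ("n_oxide", "[$([#7+][OX1-]),$([#7v5]=[OX1]);!$([#7](~[O])~[O])]"),
    ("halogen_on_aromatic", "c[F,Cl,Br,I]"),
]

_COMPILED_SMARTS = [(name, Chem.MolFromSmarts(s)) for name, s in FRAGMENT_SMARTS]

CHARGE_STAT_NAMES = ["charge_min", "charge_max", "charge_mean", "charge_std"]
GEOMETRY_STAT_NAMES = [
    "heavy_atom_count",
    "longest_distance",
    "radius_of_gyration",
    "ring_count",
    "aromatic_ring_count",
]

FEATURE_NAMES: list[str] = (
    [f"frag_{name}" for name, _ in FRAGMENT_SMARTS]
    + CHARGE_STAT_NAMES
    + GEOMETRY_STAT_NAMES
)


@dataclass
class LinkerFeatures:
    """Deterministic feature vector for one linker molecule."""

    fragment_counts: np.ndarray
    charge_stats: np.ndarray
    geometry_stats: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    version: str = FEATURE_VERSION

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.fragment_counts, self.charge_stats, self.geometry_stats])


def featurize_linker(molecule: SmallMolecule) -> LinkerFeatures:
    """Compute fragment counts, charge statistics, and geometry descriptors.

    Charges are assigned if absent; 3D coordinates are embedded from line
    notation (seeded ETKDG) if absent.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(molecule.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in molecule.bonds)
    if molecule.n_atoms > 1 and not nx.is_connected(g):
        raise ValueError("featurize_linker requires a connected molecule")

    molecule = ensure_coords(molecule)
    if np.allclose(molecule.charges, 0.0):
        molecule = assign_partial_charges(molecule)
    mol = to_rdkit(molecule)

    counts = np.array(
        [
            len(mol.GetSubstructMatches(patt, uniquify=True)) if patt is not None else 0
            for _, patt in _COMPILED_SMARTS
        ],
        dtype=float,
    )

    q = molecule.charges
    charge_stats = np.array([q.min(), q.max(), q.mean(), q.std()])

    coords = molecule.coords
    heavy = np.array([el != "H" for el in molecule.elements])
    n_heavy = int(heavy.sum())
    if molecule.n_atoms > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        longest = float(np.sqrt((diff ** 2).sum(-1)).max())
    else:
        longest = 0.0
    centroid = coords.mean(axis=0)
    rg = float(np.sqrt(((coords - centroid) ** 2).sum(axis=1).mean()))
    try:
        ring_count = rdMolDescriptors.CalcNumRings(mol)
        arom_rings = rdMolDescriptors.CalcNumAromaticRings(mol)
    except Exception:
        ring_count = len(Chem.GetSymmSSSR(mol))
        arom_rings = 0
    geometry_stats = np.array([n_heavy, longest, rg, ring_count, arom_rings], dtype=float)

    return LinkerFeatures(
        fragment_counts=counts, charge_stats=charge_stats, geometry_stats=geometry_stats
    )


# ---------------------------------------------------------------------------
# Dataset / classifier
# ---------------------------------------------------------------------------


@dataclass
class ToxicityDataset:
    """Linker-toxicity records: molecule, oral-rat LD50 (mg/kg), category label."""

    frame: pd.DataFrame  # columns: smiles, ld50_mg_per_kg, label (ToxicityCategory)
    provenance: str = "real"
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)
    bayes_accuracy: float | None = None

    def __post_init__(self):
        if (self.frame["ld50_mg_per_kg"] <= 0).any():
            raise ValueError("all LD50 values must be positive")
        derived = self.frame["ld50_mg_per_kg"].map(
            lambda x: ld50_to_custom_category(x, self.thresholds)
        )
        if not (derived == self.frame["label"]).all():
            raise ValueError("labels inconsistent with LD50 under the configured thresholds")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TrainingReport:
    accuracy: float
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    confusion: np.ndarray
    n_train: int
    n_test: int
    seed: int


@dataclass
class ToxicityClassifier:
    """Fitted three-class tree-ensemble over linker features."""

    model: RandomForestClassifier
    feature_version: str
    thresholds: CategoryThresholds
    seed: int

    def predict_proba_vector(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in (fatal, toxic, safe) order for one vector."""
        raw = self.model.predict_proba(np.asarray(x, dtype=float).reshape(1, -1))[0]
        probs = np.zeros(3)
        for cls, p in zip(self.model.classes_, raw):
            probs[int(cls)] = p
        return probs


_FEATURE_CACHE: dict[str, np.ndarray] = {}


def features_for_smiles(smiles: str) -> np.ndarray:
    """Feature vector for a SMILES string (cached: featurization is pure)."""
    if smiles not in _FEATURE_CACHE:
        from .molecules import from_smiles

        _FEATURE_CACHE[smiles] = featurize_linker(from_smiles(smiles)).vector
    return _FEATURE_CACHE[smiles]


def train_toxicity_classifier(
    dataset: ToxicityDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    n_estimators: int = 300,
) -> tuple[ToxicityClassifier, TrainingReport]:
    """Train the three-class linker classifier with a stratified held-out split."""
    if len(dataset) < 50:
        raise ValueError("need at least 50 records to train")
    labels = dataset.frame["label"].map(int).to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate single-class dataset")
    X = np.vstack([features_for_smiles(s) for s in dataset.frame["smiles"]])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, class_weight="balanced"
    )
    model.fit(X_tr, y_tr)
    y_pred = model.predict(X_te)
    acc = float((y_pred == y_te).mean())
    prec, rec, _, _ = precision_recall_fscore_support(
        y_te, y_pred, labels=[0, 1, 2], zero_division=0
    )
    names = [ToxicityCategory(i).name for i in range(3)]
    report = TrainingReport(
        accuracy=acc,
        per_class_precision=dict(zip(names, prec.tolist())),
        per_class_recall=dict(zip(names, rec.tolist())),
        confusion=confusion_matrix(y_te, y_pred, labels=[0, 1, 2]),
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=seed,
    )
    clf = ToxicityClassifier(
        model=model,
        feature_version=FEATURE_VERSION,
        thresholds=dataset.thresholds,
        seed=seed,
    )
    return clf, report


def predict_toxicity(
    classifier: ToxicityClassifier, molecule: SmallMolecule
) -> tuple[ToxicityCategory, np.ndarray]:
    """Predict the category of one linker; ties break toward the more toxic class."""
    if classifier.feature_version != FEATURE_VERSION:
        raise ValueError(
            f"model feature version {classifier.feature_version!r} does not match "
            f"featurizer version {FEATURE_VERSION!r}"
        )
    if molecule.notation:
        x = features_for_smiles(molecule.notation)
    else:
        x = featurize_linker(molecule).vector
    probs = classifier.predict_proba_vector(x)
    best = min(range(3), key=lambda i: (-probs[i], i))  # lower index = more toxic
    return ToxicityCategory(best), probs


# ---------------------------------------------------------------------------
# Metal table and whole-MOF verdict
# ---------------------------------------------------------------------------


class UnknownMetalError(KeyError):
    pass


@dataclass(frozen=True)
class MetalToxicityRecord:
    element: str
    verdict: str  # "biocompatible" | "not_biocompatible"
    note: str = ""
    representative_ld50_mg_per_kg: float | None = None


def load_metal_table(path: str | None = None) -> dict[str, MetalToxicityRecord]:
    """Load the curated metal-toxicity table (packaged CSV by default)."""
    if path is None:
        text = resources.files("mofscreen.data").joinpath("metal_toxicity.csv").read_text()
        df = pd.read_csv(io.StringIO(text))
    else:
        df = pd.read_csv(path)
    table: dict[str, MetalToxicityRecord] = {}
    for row in df.itertuples(index=False):
        ld50 = getattr(row, "representative_ld50_mg_per_kg", None)
        table[row.element] = MetalToxicityRecord(
            element=row.element,
            verdict=row.verdict,
            note=getattr(row, "note", ""),
            representative_ld50_mg_per_kg=None if pd.isna(ld50) else float(ld50),
        )
    return table


@dataclass
class BiocompatibilityReport:
    verdict: str  # "highly biocompatible" | "rejected"
    metal_verdicts: dict[str, str]  # element -> biocompatible/whitelisted/not_biocompatible
    linker_verdicts: list[dict]  # per unique linker: signature, category, probs, count
    failing_blocks: list[str]
    whitelisted: list[str]
    polymeric_linkers: int = 0

    @property
    def accepted(self) -> bool:
        return self.verdict == "highly biocompatible"


def assess_mof_biocompatibility(
    blocks: BuildingBlocks,
    metal_table: dict[str, MetalToxicityRecord],
    classifier: ToxicityClassifier,
    whitelist: tuple[str, ...] = (),
) -> BiocompatibilityReport:
    """Conjunctive verdict: all metals biocompatible (or whitelisted) AND all
    unique linkers predicted safe.

    A metal absent from the table raises :class:`UnknownMetalError` rather
    than passing silently.
    """
    metal_verdicts: dict[str, str] = {}
    failing: list[str] = []
    whitelisted: list[str] = []
    for element in sorted(blocks.metals):
        if element in whitelist:
            metal_verdicts[element] = "whitelisted"
            whitelisted.append(element)
            continue
        if element not in metal_table:
            raise UnknownMetalError(f"metal {element} not in the toxicity table")
        rec = metal_table[element]
        metal_verdicts[element] = rec.verdict
        if rec.verdict != "biocompatible":
            failing.append(f"metal:{element}")

    linker_verdicts: list[dict] = []
    for sig, mol, count in blocks.unique_linkers:
        category, probs = predict_toxicity(classifier, mol)
        linker_verdicts.append(
            {
                "signature": sig,
                "category": category.name,
                "probabilities": probs.tolist(),
                "count": count,
                "likely_solvent": sig in blocks.likely_solvent_signatures,
            }
        )
        if category != ToxicityCategory.safe:
            failing.append(f"linker:{sig[:12]}({category.name})")

    verdict = "highly biocompatible" if not failing else "rejected"
    return BiocompatibilityReport(
        verdict=verdict,
        metal_verdicts=metal_verdicts,
        linker_verdicts=linker_verdicts,
        failing_blocks=failing,
        whitelisted=whitelisted,
        polymeric_linkers=blocks.polymeric_count,
    )
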