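"""Bridging between :class:`SmallMolecule` and RDKit molecules.

RDKit is the workhorse for everything molecular: SMILES parsing, 3D
embedding (ETKDG), Gasteiger charge assignment, SMARTS substructure
matching.  This module keeps the conversions in one place.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .structures import SmallMolecule

RDLogger.DisableLog("rdApp.*")

#: Fixed seed for conformer embedding so featurization is deterministic.
EMBED_SEED = 2025


def from_smiles(smiles: str, embed3d: bool = True) -> SmallMolecule:
    """Build a :class:`SmallMolecule` (with explicit hydrogens) from SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    if embed3d:
        params = AllChem.ETKDGv3()
        params.randomSeed = EMBED_SEED
        if AllChem.EmbedMolecule(mol, params) != 0:
            # fall back to a coarser attempt with random coords
            params.useRandomCoords = True
            AllChem.EmbedMolecule(mol, params)
    return from_rdkit(mol, notation=smiles)


def from_rdkit(mol: Chem.Mol, notation: str | None = None) -> SmallMolecule:
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for atom in mol.GetAtoms():
        xyz = (
            np.array(list(conf.GetAtomPosition(atom.GetIdx())))
            if conf is not None
            else np.zeros(3)
        )
        atoms.append((atom.GetSymbol(), xyz, 0.0))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    net = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    return SmallMolecule(atoms=atoms, bonds=bonds, net_charge=net, notation=notation)


def to_rdkit(molecule: SmallMolecule, infer_bond_orders: bool = True) -> Chem.Mol:
    """Convert to an RDKit molecule, keeping 3D coordinates.

    If the molecule carries line notation it is re-parsed from that (bond
    orders are then authoritative).  Otherwise the explicit atom/bond table
    is used; with ``infer_bond_orders`` RDKit's geometry-based bond-order
    assignment is attempted and connectivity-only single bonds are the
    fallback (aromatic/multiple-bond SMARTS then simply do not match).
    """
    if molecule.notation:
        ref = Chem.MolFromSmiles(molecule.notation)
        if ref is not None:
            ref = Chem.AddHs(ref)
            if ref.GetNumAtoms() == molecule.n_atoms:
                conf = Chem.Conformer(ref.GetNumAtoms())
                for i, (_, xyz, _) in enumerate(molecule.atoms):
                    conf.SetAtomPosition(i, [float(v) for v in xyz])
                ref.RemoveAllConformers()
                ref.AddConformer(conf)
                return ref

    rw = Chem.RWMol()
    for el, _, _ in molecule.atoms:
        a = Chem.Atom(el)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in molecule.bonds:
        bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
              3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}.get(
                  float(order), Chem.BondType.SINGLE)
        rw.AddBond(int(i), int(j), bt)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (_, xyz, _) in enumerate(molecule.atoms):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.AddConformer(conf)

    if infer_bond_orders:
        try:
            from rdkit.Chem import rdDetermineBonds

            probe = Chem.Mol(mol)
            rdDetermineBonds.DetermineBondOrders(probe, charge=molecule.net_charge)
            Chem.SanitizeMol(probe)
            return probe
        except Exception:
            pass
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    except Exception:
        pass
    return mol


def ensure_coords(molecule: SmallMolecule) -> SmallMolecule:
    """Return a copy with 3D coordinates, embedding from notation if absent."""
    if molecule.n_atoms == 0:
        return molecule
    if np.allclose(molecule.coords, 0.0) and molecule.n_atoms > 1 and molecule.notation:
        return from_smiles(molecule.notation)
    return molecule
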