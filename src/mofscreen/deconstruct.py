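"""Deconstruction of a MOF into building blocks: metal centers and linkers.

Metal sites are removed, the remaining periodic bond graph is split into
connected components, each component is unwrapped across the periodic
boundary into a finite Cartesian fragment, and bonds that used to lead to a
metal are capped (default: a hydrogen on O/N/S donor atoms, restoring the
neutral protonated linker a toxicity model trained on LD50-labelled
molecules expects — a carboxylate is read back as a carboxylic acid).
Components that cannot be unwrapped (rod / polymeric ligands) are flagged
and excluded from classification.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .elements import covalent_radius, is_metal
from .structures import PeriodicStructure, SmallMolecule, periodic_bonds

__all__ = ["BuildingBlocks", "split_building_blocks", "canonical_signature"]

#: Organic components with at most this many atoms are flagged likely solvent.
SOLVENT_ATOM_LIMIT = 6


@dataclass
class BuildingBlocks:
    """Result of splitting a framework into metals and organic linkers."""

    metals: Counter
    linkers: list[SmallMolecule]
    unique_linkers: list[tuple[str, SmallMolecule, int]]  # (signature, exemplar, count)
    polymeric_count: int = 0
    likely_solvent_signatures: set[str] = field(default_factory=set)

    @property
    def n_metal_atoms(self) -> int:
        return sum(self.metals.values())


def canonical_signature(molecule: SmallMolecule) -> str:
    """Canonical text key for an element-and-bond-order-labelled graph.

    Stable across atom orderings (Weisfeiler-Lehman graph hash over element
    node labels and bond-order edge labels).  Raises on disconnected input.
    """
    g = nx.Graph()
    for i, (el, _, _) in enumerate(molecule.atoms):
        g.add_node(i, el=el)
    for i, j, order in molecule.bonds:
        g.add_edge(i, j, order=str(order))
    if g.number_of_nodes() == 0:
        raise ValueError("empty molecule has no signature")
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        raise ValueError("canonical_signature requires a connected molecule")
    return nx.weisfeiler_lehman_graph_hash(g, edge_attr="order", node_attr="el", iterations=5)


def split_building_blocks(
    structure: PeriodicStructure,
    cap: str = "protonate",
) -> BuildingBlocks:
    """Split a framework into metal atoms and unwrapped organic linkers.

    cap: ``"protonate"`` (default) adds H to O/N/S atoms that were bonded to
    a metal; ``"none"`` leaves the open valences.
    """
    if cap not in ("protonate", "none"):
        raise ValueError("cap must be 'protonate' or 'none'")
    elements = structure.elements
    metal_idx = {i for i, el in enumerate(elements) if is_metal(el)}
    metals = Counter(elements[i] for i in metal_idx)

    bonds = periodic_bonds(structure)
    # adjacency among organic atoms; remember metal contacts for capping
    adj: dict[int, list[tuple[int, np.ndarray]]] = {
        i: [] for i in range(structure.n_sites) if i not in metal_idx
    }
    metal_contacts: dict[int, list[np.ndarray]] = {}
    frac = structure.frac_coords
    for i, j, shift in bonds:
        i_metal, j_metal = i in metal_idx, j in metal_idx
        if not i_metal and not j_metal:
            adj[i].append((j, shift))
            adj[j].append((i, -shift))
        elif i_metal != j_metal:
            organic, metal = (j, i) if i_metal else (i, j)
            # fractional position of the metal image adjacent to the organic atom
            mshift = -shift if i_metal else shift
            metal_contacts.setdefault(organic, []).append(frac[metal] + mshift)

    linkers: list[SmallMolecule] = []
    polymeric = 0
    visited: set[int] = set()
    cell = structure.cell
    for seed in sorted(adj):
        if seed in visited:
            continue
        # BFS with per-atom cell offsets to unwrap the fragment
        offsets: dict[int, np.ndarray] = {seed: np.zeros(3)}
        queue = deque([seed])
        order: list[int] = [seed]
        wrapped = False
        visited.add(seed)
        while queue:
            i = queue.popleft()
            for j, shift in adj[i]:
                target = offsets[i] + shift
                if j in offsets:
                    if not np.allclose(offsets[j], target):
                        wrapped = True  # bonds to its own periodic image: polymeric
                else:
                    offsets[j] = target
                    visited.add(j)
                    order.append(j)
                    queue.append(j)
        if wrapped:
            polymeric += 1
            continue
        index_of = {atom: k for k, atom in enumerate(order)}
        atoms = [
            (elements[i], cell.frac_to_cart(frac[i] + offsets[i]), 0.0) for i in order
        ]
        mol_bonds = [
            (index_of[i], index_of[j], 1.0)
            for i in order
            for j, _ in adj[i]
            if index_of[i] < index_of[j]
        ]
        if cap == "protonate":
            for i in order:
                if elements[i] not in ("O", "N", "S"):
                    continue
                for metal_frac in metal_contacts.get(i, []):
                    donor = cell.frac_to_cart(frac[i] + offsets[i])
                    toward = cell.frac_to_cart(metal_frac + offsets[i]) - donor
                    norm = np.linalg.norm(toward)
                    u = toward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
                    d = covalent_radius(elements[i]) + covalent_radius("H")
                    atoms.append(("H", donor + u * d, 0.0))
                    mol_bonds.append((index_of[i], len(atoms) - 1, 1.0))
        linkers.append(SmallMolecule(atoms=atoms, bonds=mol_bonds, net_charge=0))

    # deduplicate by canonical signature
    seen: dict[str, tuple[SmallMolecule, int]] = {}
    solvent_sigs: set[str] = set()
    sig_order: list[str] = []
    for mol in linkers:
        sig = canonical_signature(mol)
        n_heavy = sum(1 for el in mol.elements if el != "H")
        if n_heavy <= SOLVENT_ATOM_LIMIT:
            solvent_sigs.add(sig)
        if sig in seen:
            exemplar, count = seen[sig]
            seen[sig] = (exemplar, count + 1)
        else:
            seen[sig] = (mol, 1)
            sig_order.append(sig)
    unique = [(sig, seen[sig][0], seen[sig][1]) for sig in sorted(sig_order)]

    return BuildingBlocks(
        metals=metals,
        linkers=linkers,
        unique_linkers=unique,
        polymeric_count=polymeric,
        likely_solvent_signatures=solvent_sigs,
    )
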