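"""Perception of conjugated subsystems and conjugation descriptors.

A conjugated system is a connected set of bonds carrying delocalized pi
electrons: aromatic bonds, multiple bonds, and single bonds bridging them
(including heteroatom lone pairs in conjugation, as in aniline's C-N bond).
Perception relies on the toolkit's conjugated-bond flags; an isolated
multiple bond, which the flagging scheme leaves unflagged, is still
perceived as its own (minimal) system.

The descriptor the downstream model cares most about is the *conjugation
length* ``Conju-Max-Distance``: the number of bonds linking the farthest
atom pair within one conjugated system (the graph diameter of the system's
induced subgraph).  Other descriptors summarize size (conjugated weight and
surface area), shape (branching of the largest system) and composition
(heteroatom and aromatic fractions).

Donor/acceptor assignment matches an editable SMARTS pattern library and
reports ``DAratio``: the bond-path distance between donor and acceptor
atoms inside the conjugated system, divided by the conjugation length --
close to 1 for a dipolar D-pi-A rod, close to 0.5 for a quadrupolar D-A-D.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors, Descriptors

__all__ = [
    "ConjugatedSystem",
    "DonorAcceptorAssignment",
    "perceive_conjugated_systems",
    "conju_max_distance",
    "conju_branch_ratio",
    "conju_weights_and_area",
    "assign_donor_acceptor",
    "conjugation_features",
    "load_pattern_library",
    "CONJUGATION_FEATURE_NAMES",
]


@dataclass(frozen=True)
class ConjugatedSystem:
    """One connected conjugated unit of a molecule.

    ``minimal`` flags systems of fewer than 3 atoms (a lone multiple bond).
    """

    atom_indices: frozenset[int]
    bond_indices: frozenset[int]
    minimal: bool

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class DonorAcceptorAssignment:
    donor_atoms: frozenset[int]
    acceptor_atoms: frozenset[int]
    da_distance: int
    daratio: float
    defined: bool


def perceive_conjugated_systems(mol: Chem.Mol) -> list[ConjugatedSystem]:
    """Connected components of the conjugated-bond subgraph.

    Bonds are included when the toolkit flags them conjugated or when their
    order exceeds one (so an isolated double bond forms a minimal system).
    Systems are ordered by size descending, ties by smallest atom index.
    """
    edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetIdx())
        for b in mol.GetBonds()
        if b.GetIsConjugated() or b.GetBondTypeAsDouble() > 1.0
    ]
    if not edges:
        return []
    g = nx.Graph()
    for u, v, idx in edges:
        g.add_edge(u, v, bond=idx)
    systems = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        bonds = frozenset(d["bond"] for _, _, d in sub.edges(data=True))
        systems.append(
            ConjugatedSystem(
                atom_indices=frozenset(comp),
                bond_indices=bonds,
                minimal=len(comp) < 3,
            )
        )
    systems.sort(key=lambda s: (-len(s.atom_indices), min(s.atom_indices)))
    return systems


def _system_graph(mol: Chem.Mol, system: ConjugatedSystem) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(system.atom_indices)
    for idx in system.bond_indices:
        b = mol.GetBondWithIdx(idx)
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return g


def conju_max_distance(mol: Chem.Mol, systems: list[ConjugatedSystem] | None = None) -> int:
    """Maximum over systems of the bond-count graph diameter; 0 if none."""
    if systems is None:
        systems = perceive_conjugated_systems(mol)
    best = 0
    for system in systems:
        g = _system_graph(mol, system)
        ecc = nx.eccentricity(g)
        best = max(best, max(ecc.values()))
    return best


def conju_branch_ratio(mol: Chem.Mol, systems: list[ConjugatedSystem] | None = None) -> float:
    """Fraction of atoms in the largest system with within-system degree >= 3.

    0 for any linear or simple-ring system; positive for branched
    (multipolar) conjugation topologies.  0 for molecules with no system.
    """
    if systems is None:
        systems = perceive_conjugated_systems(mol)
    if not systems:
        return 0.0
    g = _system_graph(mol, systems[0])
    n_branch = sum(1 for _, d in g.degree() if d >= 3)
    return n_branch / g.number_of_nodes()


def _atom_mass_with_hs(atom: Chem.Atom) -> float:
    return atom.GetMass() + 1.008 * atom.GetTotalNumHs()


def conju_weights_and_area(
    mol: Chem.Mol, systems: list[ConjugatedSystem] | None = None
) -> tuple[float, float, float, float]:
    """Return (conju_wt, conju_atom_wt, conju_stru_vsa, full_wt).

    conju_wt: summed atomic masses (with implicit H) over conjugated atoms,
    g/mol.  conju_atom_wt: molecular weight per heavy atom, g/mol.
    conju_stru_vsa: summed approximate van-der-Waals surface (Labute ASA
    heavy-atom contributions) over conjugated atoms, A^2.  full_wt:
    molecular weight, g/mol.
    """
    if systems is None:
        systems = perceive_conjugated_systems(mol)
    conj_atoms = set().union(*(s.atom_indices for s in systems)) if systems else set()
    full_wt = Descriptors.MolWt(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    conju_atom_wt = full_wt / n_heavy if n_heavy else 0.0
    conju_wt = sum(
        _atom_mass_with_hs(mol.GetAtomWithIdx(i)) for i in conj_atoms
    )
    asa_contribs = rdMolDescriptors._CalcLabuteASAContribs(mol)[0]
    conju_stru_vsa = float(sum(asa_contribs[i] for i in conj_atoms))
    return conju_wt, conju_atom_wt, conju_stru_vsa, full_wt


def load_pattern_library(path: str | Path | None = None) -> list[tuple[Chem.Mol, str]]:
    """Load the donor/acceptor SMARTS library (pattern, role) pairs."""
    if path is None:
        text = resources.files("tpascreen.data").joinpath("da_patterns.smarts").read_text()
    else:
        text = Path(path).read_text()
    library = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smarts, role = line.split()
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in pattern library: {smarts!r}")
        if role not in ("donor", "acceptor"):
            raise ValueError(f"invalid role {role!r} for pattern {smarts!r}")
        library.append((patt, role))
    return library


_DEFAULT_PATTERNS: list[tuple[Chem.Mol, str]] | None = None


def _default_patterns() -> list[tuple[Chem.Mol, str]]:
    global _DEFAULT_PATTERNS
    if _DEFAULT_PATTERNS is None:
        _DEFAULT_PATTERNS = load_pattern_library()
    return _DEFAULT_PATTERNS


def assign_donor_acceptor(
    mol: Chem.Mol,
    systems: list[ConjugatedSystem] | None = None,
    pattern_library: list[tuple[Chem.Mol, str]] | None = None,
    span: str = "max",
) -> DonorAcceptorAssignment:
    """Locate donor/acceptor atoms inside the largest conjugated system.

    ``da_distance`` is the max (default) or min over donor-acceptor atom
    pairs of the shortest-path bond count restricted to the system;
    ``daratio`` divides it by the system diameter.  When either role has no
    match inside the system the assignment is flagged undefined and the
    ratio is 0.
    """
    if systems is None:
        systems = perceive_conjugated_systems(mol)
    if pattern_library is None:
        pattern_library = _default_patterns()
    if span not in ("max", "min"):
        raise ValueError(f"span must be 'max' or 'min', got {span!r}")
    if not systems:
        return DonorAcceptorAssignment(frozenset(), frozenset(), 0, 0.0, False)

    system = systems[0]
    donors: set[int] = set()
    acceptors: set[int] = set()
    for patt, role in pattern_library:
        for match in mol.GetSubstructMatches(patt):
            hit = set(match) & system.atom_indices
            (donors if role == "donor" else acceptors).update(hit)
    # an atom matched by both roles (e.g. aniline N in a sulfonamide) is ambiguous; drop it
    ambiguous = donors & acceptors
    donors -= ambiguous
    acceptors -= ambiguous
    if not donors or not acceptors:
        return DonorAcceptorAssignment(
            frozenset(donors), frozenset(acceptors), 0, 0.0, False
        )

    g = _system_graph(mol, system)
    diameter = max(nx.eccentricity(g).values())
    dists = []
    for d in donors:
        lengths = nx.single_source_shortest_path_length(g, d)
        dists.extend(lengths[a] for a in acceptors)
    da_distance = max(dists) if span == "max" else min(dists)
    daratio = da_distance / diameter if diameter else 0.0
    return DonorAcceptorAssignment(
        frozenset(donors), frozenset(acceptors), int(da_distance), float(daratio), True
    )


#: Ordered roster of the conjugation descriptor block.  The first seven are
#: pinned by the formulas above; the remainder are complementary size/shape/
#: composition summaries of the perceived systems (approximate registry).
CONJUGATION_FEATURE_NAMES = [
    "Conju-Max-Distance",
    "Conju-Branch-Ratio",
    "Conju-Atom-Wt",
    "Conju-Wt",
    "Conju-Stru-VSA",
    "Full-Wt",
    "Conju-N-Systems",
    "Conju-Atom-Count",
    "Conju-Bond-Count",
    "Conju-Atom-Fraction",
    "Conju-Wt-Ratio",
    "Conju-Largest-System-Atoms",
    "Conju-Mean-System-Size",
    "Conju-Aromatic-Ring-Count",
    "Conju-Hetero-Count",
    "Conju-Hetero-Fraction",
    "Conju-Branch-Count",
    "Conju-Terminal-Count",
    "Conju-Length-Per-Atom",
    "Conju-Cyclicity",
    "Conju-Aromatic-Fraction",
]


def conjugation_features(mol: Chem.Mol) -> dict[str, float]:
    """Compute the full conjugation descriptor block for one molecule."""
    systems = perceive_conjugated_systems(mol)
    conj_atoms = set().union(*(s.atom_indices for s in systems)) if systems else set()
    conju_wt, conju_atom_wt, conju_stru_vsa, full_wt = conju_weights_and_area(
        mol, systems
    )
    l_max = conju_max_distance(mol, systems)
    n_heavy = mol.GetNumHeavyAtoms()
    n_conj = len(conj_atoms)
    n_bonds = sum(len(s.bond_indices) for s in systems)

    if systems:
        g0 = _system_graph(mol, systems[0])
        degs = dict(g0.degree())
        n_branch = sum(1 for d in degs.values() if d >= 3)
        n_terminal = sum(1 for d in degs.values() if d == 1)
        largest = g0.number_of_nodes()
        mean_size = n_conj / len(systems)
        cyclicity = g0.number_of_edges() - largest + 1  # independent cycles
    else:
        n_branch = n_terminal = largest = 0
        mean_size = 0.0
        cyclicity = 0

    n_hetero = sum(
        1 for i in conj_atoms if mol.GetAtomWithIdx(i).GetAtomicNum() != 6
    )
    n_aromatic = sum(
        1 for i in conj_atoms if mol.GetAtomWithIdx(i).GetIsAromatic()
    )
    ring_info = mol.GetRingInfo()
    n_arom_rings = sum(
        1
        for ring in ring_info.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )

    return {
        "Conju-Max-Distance": float(l_max),
        "Conju-Branch-Ratio": conju_branch_ratio(mol, systems),
        "Conju-Atom-Wt": conju_atom_wt,
        "Conju-Wt": conju_wt,
        "Conju-Stru-VSA": conju_stru_vsa,
        "Full-Wt": full_wt,
        "Conju-N-Systems": float(len(systems)),
        "Conju-Atom-Count": float(n_conj),
        "Conju-Bond-Count": float(n_bonds),
        "Conju-Atom-Fraction": n_conj / n_heavy if n_heavy else 0.0,
        "Conju-Wt-Ratio": conju_wt / full_wt if full_wt else 0.0,
        "Conju-Largest-System-Atoms": float(largest),
        "Conju-Mean-System-Size": float(mean_size),
        "Conju-Aromatic-Ring-Count": float(n_arom_rings),
        "Conju-Hetero-Count": float(n_hetero),
        "Conju-Hetero-Fraction": n_hetero / n_conj if n_conj else 0.0,
        "Conju-Branch-Count": float(n_branch),
        "Conju-Terminal-Count": float(n_terminal),
        "Conju-Length-Per-Atom": l_max / largest if largest else 0.0,
        "Conju-Cyclicity": float(cyclicity),
        "Conju-Aromatic-Fraction": n_aromatic / n_conj if n_conj else 0.0,
    }
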