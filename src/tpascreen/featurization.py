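"""Molecular featurization: fragment counts, attributed properties, 2D descriptors.

The molecular fragment fingerprint (MFF) enumerates every atom-centered
environment of radius 0..R (extended-connectivity style) and renders each as
a standalone canonical substructure string -- the context beyond the
environment is deliberately discarded, so identical local fragments from
different molecules collide onto one catalog key.  A molecule's MFF vector
records how many times each catalog fragment appears.

MFF-MOE features project atom-attributable properties (Gasteiger/PEOE
partial charge, Crippen LogP and molar refractivity MR, Labute surface
area) onto the fragments: each fragment instance gets the sum of its atoms'
contributions, and the per-molecule feature is an aggregate (max/min/mean/
sum) of those fragment sums.  "PEOE-Charge-Max", for example, is the most
positive fragment-summed Gasteiger charge in the molecule.

The general descriptor block is a pinned 107-name manifest of standard
whole-molecule 2D descriptors, so feature matrices stay reproducible across
toolkit upgrades.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors, rdPartialCharges

from .conjugation import conjugation_features, perceive_conjugated_systems
from .dataset_io import ModellingSample

__all__ = [
    "FragmentCatalog",
    "MFFVector",
    "FeatureMatrix",
    "fragment_environments",
    "build_catalog",
    "mff_featurize",
    "atom_attributions",
    "mff_moe_features",
    "general_descriptors",
    "descriptor_manifest",
    "assemble_matrix",
    "ATTRIBUTABLE_PROPERTIES",
    "DEFAULT_AGGREGATIONS",
]

ATTRIBUTABLE_PROPERTIES = ("PEOE-Charge", "LogP", "MR", "ASA")
DEFAULT_AGGREGATIONS = ("Max", "Min", "Mean", "Sum")


@dataclass
class FragmentCatalog:
    """Ordered vocabulary of canonical fragment keys.

    Keys are canonical substructure SMILES of atom-centered environments;
    order is lexicographic, making two builds from the same corpus
    byte-identical.
    """

    entries: dict[str, int]
    radius: int
    min_support: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keys(self) -> list[str]:
        return list(self.entries)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "radius": self.radius,
                    "min_support": self.min_support,
                    "entries": self.entries,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FragmentCatalog":
        raw = json.loads(Path(path).read_text())
        return cls(
            entries=dict(raw["entries"]),
            radius=int(raw["radius"]),
            min_support=int(raw["min_support"]),
        )


@dataclass
class MFFVector:
    """Sparse non-negative fragment counts against a catalog."""

    counts: dict[int, int]
    n_features: int

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.n_features, dtype=np.int64)
        for idx, c in self.counts.items():
            v[idx] = c
        return v


def fragment_environments(
    mol: Chem.Mol, radius: int
) -> list[tuple[str, tuple[int, ...]]]:
    """Enumerate all atom-centered environments of radius 0..radius.

    Returns (canonical fragment key, atom index tuple) per environment
    instance.  Radius-0 environments are single heavy atoms; for r >= 1 the
    environment is the set of bonds within r of the center atom.  An
    environment that does not grow when r increases (the whole fragment
    already captured) is emitted only once, at the smallest radius.
    """
    out: list[tuple[str, tuple[int, ...]]] = []
    for atom in mol.GetAtoms():
        center = atom.GetIdx()
        seen_bond_sets: set[frozenset[int]] = set()
        for r in range(radius + 1):
            if r == 0:
                atoms: tuple[int, ...] = (center,)
                bonds: list[int] = []
            else:
                bonds = list(Chem.FindAtomEnvironmentOfRadiusN(mol, r, center))
                if not bonds:
                    break
                key_bonds = frozenset(bonds)
                if key_bonds in seen_bond_sets:
                    continue
                seen_bond_sets.add(key_bonds)
                amap: set[int] = set()
                for bidx in bonds:
                    b = mol.GetBondWithIdx(bidx)
                    amap.add(b.GetBeginAtomIdx())
                    amap.add(b.GetEndAtomIdx())
                atoms = tuple(sorted(amap))
            key = Chem.MolFragmentToSmiles(
                mol,
                atomsToUse=list(atoms),
                bondsToUse=bonds or None,
                canonical=True,
            )
            out.append((key, atoms))
    return out


def build_catalog(
    molecules: Sequence[Chem.Mol], radius: int = 4, min_support: int = 2
) -> FragmentCatalog:
    """Build a fragment catalog from a molecule corpus.

    A key enters the catalog when it occurs in at least ``min_support``
    distinct molecules.  Ordering is lexicographic by key.
    """
    if not molecules:
        raise ValueError("cannot build a catalog from an empty molecule list")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    support: dict[str, int] = {}
    for mol in molecules:
        mol_keys = {key for key, _ in fragment_environments(mol, radius)}
        for key in mol_keys:
            support[key] = support.get(key, 0) + 1
    kept = sorted(k for k, s in support.items() if s >= min_support)
    return FragmentCatalog(
        entries={k: i for i, k in enumerate(kept)},
        radius=radius,
        min_support=min_support,
    )


def mff_featurize(mol: Chem.Mol, catalog: FragmentCatalog) -> MFFVector:
    """Count catalog fragments in a molecule; off-catalog environments are ignored."""
    counts: dict[int, int] = {}
    for key, _ in fragment_environments(mol, catalog.radius):
        idx = catalog.entries.get(key)
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    return MFFVector(counts=counts, n_features=len(catalog))


class UnparameterizedAtomError(ValueError):
    """An atom type falls outside the attribution scheme's parameter table."""


def atom_attributions(mol: Chem.Mol, property_name: str) -> np.ndarray:
    """Per-heavy-atom contributions of an attributable property.

    Hydrogens are folded into their heavy-atom neighbors.  Supported:
    ``PEOE-Charge`` (Gasteiger charges, e), ``LogP`` (Crippen octanol-water
    contributions), ``MR`` (Crippen molar refractivity, cm^3/mol), ``ASA``
    (Labute approximate surface area, A^2).
    """
    name = property_name.lower().replace("_", "-")
    n = mol.GetNumAtoms()
    if name in ("peoe-charge", "peoe"):
        rdPartialCharges.ComputeGasteigerCharges(mol)
        vals = np.empty(n)
        for i, atom in enumerate(mol.GetAtoms()):
            q = atom.GetDoubleProp("_GasteigerCharge")
            qh = atom.GetDoubleProp("_GasteigerHCharge")
            vals[i] = q + qh
        if not np.all(np.isfinite(vals)):
            raise UnparameterizedAtomError(
                "Gasteiger charges undefined for some atoms of "
                f"{Chem.MolToSmiles(mol)}"
            )
        return vals
    if name in ("logp", "mr"):
        molh = Chem.AddHs(mol)
        contribs = rdMolDescriptors._CalcCrippenContribs(molh)
        col = 0 if name == "logp" else 1
        vals = np.zeros(n)
        for atom in molh.GetAtoms():
            v = contribs[atom.GetIdx()][col]
            if atom.GetAtomicNum() == 1:
                nbr = atom.GetNeighbors()[0].GetIdx()
                if nbr < n:
                    vals[nbr] += v
            else:
                vals[atom.GetIdx()] += v
        if not np.all(np.isfinite(vals)):
            raise UnparameterizedAtomError(
                f"Crippen {name} contributions undefined for "
                f"{Chem.MolToSmiles(mol)}"
            )
        return vals
    if name == "asa":
        heavy, _ = rdMolDescriptors._CalcLabuteASAContribs(mol)
        return np.asarray(list(heavy), dtype=float)
    raise ValueError(
        f"unsupported property {property_name!r}; "
        f"supported: {ATTRIBUTABLE_PROPERTIES}"
    )


def mff_moe_features(
    mol: Chem.Mol,
    catalog: FragmentCatalog,
    attribution: np.ndarray,
    property_name: str,
    aggregations: Sequence[str] = DEFAULT_AGGREGATIONS,
    scope: str = "all",
) -> dict[str, float]:
    """Aggregate fragment-summed atomic contributions per molecule.

    For every catalog fragment instance, the fragment sum is the sum of the
    attribution over the instance's atoms; the requested aggregations
    (Max/Min/Mean/Sum) of those sums form the features.  ``scope='conjugated'``
    restricts to instances centered on a conjugated atom.  A molecule with no
    catalog fragment yields 0 for every aggregate (degenerate input).
    """
    if scope not in ("all", "conjugated"):
        raise ValueError(f"scope must be 'all' or 'conjugated', got {scope!r}")
    conj_atoms: set[int] | None = None
    if scope == "conjugated":
        systems = perceive_conjugated_systems(mol)
        conj_atoms = set().union(*(s.atom_indices for s in systems)) if systems else set()

    sums: list[float] = []
    for key, atoms in fragment_environments(mol, catalog.radius):
        if key not in catalog.entries:
            continue
        if conj_atoms is not None and atoms[0] not in conj_atoms:
            # radius-0 instances are centered on their single atom; larger
            # environments keep the center in the atom tuple
            if not set(atoms) & conj_atoms:
                continue
        sums.append(float(attribution[list(atoms)].sum()))

    suffix = "" if scope == "all" else "-Conj"
    agg_funcs = {"Max": max, "Min": min, "Mean": lambda v: sum(v) / len(v), "Sum": sum}
    out = {}
    for agg in aggregations:
        name = f"{property_name}-{agg}{suffix}"
        out[name] = float(agg_funcs[agg](sums)) if sums else 0.0
    return out


def descriptor_manifest() -> list[str]:
    """The pinned 107-descriptor roster (stable order)."""
    raw = json.loads(
        resources.files("tpascreen.data").joinpath("descriptor_manifest.json").read_text()
    )
    return list(raw["names"])


_DESC_FUNCS = dict(Descriptors._descList)


def general_descriptors(mol: Chem.Mol) -> pd.Series:
    """Whole-molecule 2D descriptor block per the pinned manifest.

    A descriptor that fails to compute yields NaN here and is imputed at
    matrix assembly.
    """
    names = descriptor_manifest()
    values = np.empty(len(names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(names):
            try:
                v = _DESC_FUNCS[name](mol)
            except Exception:
                v = np.nan
            values[i] = v if v is not None else np.nan
    return pd.Series(values, index=names)


@dataclass
class FeatureMatrix:
    """Named samples x named features with per-column block provenance."""

    df: pd.DataFrame
    blocks: dict[str, str] = field(default_factory=dict)  # feature -> block tag

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def block(self, tag: str) -> list[str]:
        return [f for f, t in self.blocks.items() if t == tag]

    def select(self, features: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            df=self.df[list(features)].copy(),
            blocks={f: self.blocks[f] for f in features},
        )

    def with_column(self, name: str, values: np.ndarray, tag: str = "extra") -> "FeatureMatrix":
        if name in self.df.columns:
            raise ValueError(f"duplicate feature name {name!r}")
        df = self.df.copy()
        df[name] = values
        blocks = dict(self.blocks)
        blocks[name] = tag
        return FeatureMatrix(df=df, blocks=blocks)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="sample_id")

    def write_mff_triplets(self, path: str | Path) -> None:
        """Sparse (sample_id, fragment, count) export of the MFF block."""
        cols = self.block("mff")
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("sample_id\tfragment\tcount\n")
            for sid, row in self.df[cols].iterrows():
                for name, v in row.items():
                    if v:
                        fh.write(f"{sid}\t{name[4:]}\t{int(v)}\n")  # strip "MFF:"

    def manifest(self) -> dict:
        return {"features": [{"name": f, "block": t} for f, t in self.blocks.items()]}


def _impute_median(df: pd.DataFrame) -> pd.DataFrame:
    """Column-median imputation; an all-NaN column becomes 0."""
    df = df.replace([np.inf, -np.inf], np.nan)
    med = df.median(axis=0)
    med = med.fillna(0.0)
    return df.fillna(med)


def assemble_matrix(
    samples: Sequence[ModellingSample],
    catalog: FragmentCatalog | None = None,
    blocks: Sequence[str] = ("mff", "general", "conjugation", "experimental"),
    include_mff_moe: bool = False,
    moe_properties: Sequence[str] = ("PEOE-Charge", "LogP", "MR", "ASA"),
    moe_aggregations: Sequence[str] = DEFAULT_AGGREGATIONS,
    moe_scopes: Sequence[str] = ("all", "conjugated"),
) -> FeatureMatrix:
    """Assemble the full feature matrix for a sample list.

    Column blocks are concatenated in the fixed order
    MFF | general | conjugation | (mff-moe) | solvent + wavelength, with
    provenance tags; median imputation guarantees a complete matrix.
    ``catalog`` is required when the ``mff`` block (or MFF-MOE) is requested.
    """
    if ("mff" in blocks or include_mff_moe) and catalog is None:
        raise ValueError("a FragmentCatalog is required for MFF / MFF-MOE blocks")

    mols = []
    for s in samples:
        mol = Chem.MolFromSmiles(s.smiles)
        if mol is None:
            raise ValueError(f"sample {s.molecule_id}: SMILES does not parse")
        mols.append(mol)

    ids = [s.molecule_id for s in samples]
    pieces: list[pd.DataFrame] = []
    tags: dict[str, str] = {}

    if "mff" in blocks:
        assert catalog is not None
        mff = np.vstack([mff_featurize(m, catalog).to_dense() for m in mols])
        names = [f"MFF:{k}" for k in catalog.keys]
        pieces.append(pd.DataFrame(mff, index=ids, columns=names, dtype=float))
        tags.update({n: "mff" for n in names})

    if "general" in blocks:
        gen = pd.DataFrame(
            [general_descriptors(m) for m in mols], index=ids
        )
        pieces.append(gen)
        tags.update({n: "general" for n in gen.columns})

    if "conjugation" in blocks:
        conj = pd.DataFrame(
            [conjugation_features(m) for m in mols], index=ids
        )
        pieces.append(conj)
        tags.update({n: "conjugation" for n in conj.columns})

    if include_mff_moe:
        assert catalog is not None
        rows = []
        for m in mols:
            feats: dict[str, float] = {}
            for prop in moe_properties:
                attr = atom_attributions(m, prop)
                for scope in moe_scopes:
                    feats.update(
                        mff_moe_features(
                            m, catalog, attr, prop, moe_aggregations, scope
                        )
                    )
            rows.append(feats)
        moe = pd.DataFrame(rows, index=ids)
        pieces.append(moe)
        tags.update({n: "mff-moe" for n in moe.columns})

    if "experimental" in blocks:
        exp = pd.DataFrame(
            {
                "ET(30)": [s.solvent.et30 for s in samples],
                "Dielectric": [s.solvent.dielectric for s in samples],
                "Dipole": [s.solvent.dipole for s in samples],
                "Wavelength": [s.wavelength for s in samples],
            },
            index=ids,
        )
        pieces.append(exp)
        tags.update({n: "experimental" for n in exp.columns})

    df = pd.concat(pieces, axis=1)
    dup = df.columns[df.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature names: {sorted(set(dup))}")
    df = _impute_median(df)
    return FeatureMatrix(df=df, blocks=tags)
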