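"""Reading, validation and restructuring of experimental TPACS measurement tables.

The experimental literature reports two-photon absorption cross sections
(TPACS, in GM) of chromophores measured at one or several wavelengths in a
named solvent.  This module turns such a table into modelling samples:

* rows are validated (SMILES must parse, the cross section must be positive)
  and rejected rows are collected into a machine-readable report;
* records can be filtered by wavelength window and by banned elements;
* multi-wavelength molecules are collapsed to one sample per unique molecule
  (canonical-SMILES identity) under a configurable policy;
* solvents are encoded by three polarity descriptors -- ET(30), the static
  dielectric constant and the dipole moment -- from an embedded literature
  table;
* the cross section is moved to log10 units (``lg_tpacs``), the scale on
  which all modelling happens.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MeasurementRecord",
    "SolventDescriptor",
    "ModellingSample",
    "RejectionReport",
    "DEFAULT_DIALECT",
    "read_measurements",
    "write_measurements",
    "filter_measurements",
    "collapse_to_samples",
    "encode_solvent",
    "known_solvents",
    "canonical_smiles",
    "write_samples",
]

#: Default column mapping for the deposited-measurement-table dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "smiles": "SMILES",
    "tpacs": "TPACS/GM",
    "wavelength": "Wavelength/nm",
    "solvent": "Solvent",
    "method": "Method",
    "doi": "DOI",
}

#: Default wavelength window (nm) and banned elements for the dataset filter.
DEFAULT_LAMBDA_MIN = 600.0
DEFAULT_LAMBDA_MAX = 1100.0
DEFAULT_BANNED_ELEMENTS = ("P", "Si", "I")


@dataclass(frozen=True)
class MeasurementRecord:
    """One experimental TPACS observation."""

    smiles: str
    tpacs: float          # cross section, GM
    wavelength: float     # excitation wavelength, nm
    solvent: str
    method: str | None = None
    doi: str | None = None

    def __post_init__(self) -> None:
        if not self.tpacs > 0:
            raise ValueError(f"tpacs must be positive, got {self.tpacs}")
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")


@dataclass(frozen=True)
class SolventDescriptor:
    """Three-descriptor polarity encoding of a solvent."""

    name: str
    et30: float        # kcal/mol
    dielectric: float  # dimensionless
    dipole: float      # Debye

    def __post_init__(self) -> None:
        for f_name in ("et30", "dielectric", "dipole"):
            v = getattr(self, f_name)
            if not math.isfinite(v):
                raise ValueError(f"{f_name} must be finite, got {v}")


@dataclass(frozen=True)
class ModellingSample:
    """One molecule with its selected measurement, in lg units."""

    molecule_id: str
    smiles: str
    lg_tpacs: float
    wavelength: float
    solvent: SolventDescriptor


@dataclass
class RejectionReport:
    """Accounting of dropped rows; never silently discarded."""

    n_read: int = 0
    n_kept: int = 0
    rejections: list[dict] = field(default_factory=list)

    def add(self, row_number: int, reason: str, row: dict) -> None:
        self.rejections.append({"row": row_number, "reason": reason, "data": row})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class UnknownSolventError(KeyError):
    """A solvent label is absent from the constants table."""


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES used as molecule identity.

    Standardization keeps the largest covalent fragment (salts and
    counter-ions stripped); returns None when the input does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


def read_measurements(
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> tuple[list[MeasurementRecord], RejectionReport]:
    """Read a measurement CSV into validated records.

    Rows with unparsable SMILES, non-positive cross sections or non-numeric
    fields are dropped and itemized in the returned :class:`RejectionReport`.

    Raises :class:`SchemaError` naming the first missing required column and
    ``ValueError`` on an empty file.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"empty input file: {path}")
        header = list(reader.fieldnames)
        for key in ("smiles", "tpacs", "wavelength", "solvent"):
            if dialect[key] not in header:
                raise SchemaError(
                    f"required column {dialect[key]!r} (field {key!r}) "
                    f"missing from {path}; found {header}"
                )
        rows = list(reader)
    if not rows:
        raise ValueError(f"no data rows in input file: {path}")

    report = RejectionReport(n_read=len(rows))
    records: list[MeasurementRecord] = []
    for i, row in enumerate(rows, start=2):  # 1-based, after header
        smi = (row.get(dialect["smiles"]) or "").strip()
        try:
            sigma = float(row[dialect["tpacs"]])
            lam = float(row[dialect["wavelength"]])
        except (TypeError, ValueError):
            report.add(i, "non-numeric tpacs or wavelength", row)
            continue
        if sigma <= 0:
            report.add(i, f"non-positive tpacs ({sigma})", row)
            continue
        if lam <= 0:
            report.add(i, f"non-positive wavelength ({lam})", row)
            continue
        if Chem.MolFromSmiles(smi) is None:
            report.add(i, f"SMILES parse failure ({smi!r})", row)
            continue
        records.append(
            MeasurementRecord(
                smiles=smi,
                tpacs=sigma,
                wavelength=lam,
                solvent=(row.get(dialect["solvent"]) or "").strip(),
                method=(row.get(dialect.get("method", "")) or None),
                doi=(row.get(dialect.get("doi", "")) or None),
            )
        )
    report.n_kept = len(records)
    return records, report


def write_measurements(
    records: Iterable[MeasurementRecord],
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> None:
    """Write records back to the CSV dialect (round-trips with read)."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    fields = ["smiles", "tpacs", "wavelength", "solvent", "method", "doi"]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([dialect[f] for f in fields])
        for rec in records:
            writer.writerow(
                [rec.smiles, repr(rec.tpacs), repr(rec.wavelength),
                 rec.solvent, rec.method or "", rec.doi or ""]
            )


def _contains_banned_element(smiles: str, banned: Sequence[str]) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return True
    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
    return bool(symbols.intersection(banned))


def filter_measurements(
    records: Sequence[MeasurementRecord],
    lambda_min: float = DEFAULT_LAMBDA_MIN,
    lambda_max: float = DEFAULT_LAMBDA_MAX,
    banned_elements: Sequence[str] = DEFAULT_BANNED_ELEMENTS,
) -> list[MeasurementRecord]:
    """Keep records inside [lambda_min, lambda_max] nm whose molecules contain
    no banned element.  Idempotent; an empty result is allowed."""
    if not lambda_min < lambda_max:
        raise ValueError("lambda_min must be < lambda_max")
    banned = tuple(banned_elements)
    return [
        rec
        for rec in records
        if lambda_min <= rec.wavelength <= lambda_max
        and not _contains_banned_element(rec.smiles, banned)
    ]


def _load_solvent_table() -> tuple[dict[str, SolventDescriptor], dict[str, str]]:
    raw = json.loads(
        resources.files("tpascreen.data").joinpath("solvents.json").read_text()
    )
    table = {
        name: SolventDescriptor(name=name, **vals)
        for name, vals in raw["solvents"].items()
    }
    return table, dict(raw["aliases"])


_SOLVENT_TABLE, _SOLVENT_ALIASES = _load_solvent_table()


def known_solvents() -> list[str]:
    return sorted(_SOLVENT_TABLE)


def _normalize_solvent_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


def encode_solvent(
    name: str, table: dict[str, SolventDescriptor] | None = None
) -> SolventDescriptor:
    """Look up the (ET(30), dielectric, dipole) descriptor triple for a solvent.

    Matching is case-insensitive and alias-aware ("DCM" -> dichloromethane).
    Raises :class:`UnknownSolventError` listing the known names otherwise.
    """
    table = _SOLVENT_TABLE if table is None else table
    key = _normalize_solvent_name(name)
    key = _SOLVENT_ALIASES.get(key, key)
    if key not in table:
        raise UnknownSolventError(
            f"unknown solvent {name!r}; known: {', '.join(sorted(table))}"
        )
    return table[key]


def collapse_to_samples(
    records: Sequence[MeasurementRecord],
    policy: str = "max-sigma",
    target_wavelength: float = 800.0,
    solvent_table: dict[str, SolventDescriptor] | None = None,
) -> list[ModellingSample]:
    """Collapse measurements to exactly one sample per unique molecule.

    Molecule identity is the canonical SMILES.  Policies:

    ``max-sigma``
        keep the record with the largest cross section (the screening-
        relevant peak value); ties broken by lower wavelength.
    ``nearest-wavelength``
        keep the record measured closest to ``target_wavelength``.

    The kept record's cross section is moved to lg units.  Raises
    :class:`UnknownSolventError` if any kept record's solvent is not in the
    constants table.
    """
    if policy not in ("max-sigma", "nearest-wavelength"):
        raise ValueError(f"unknown collapse policy {policy!r}")

    groups: dict[str, list[MeasurementRecord]] = {}
    for rec in records:
        can = canonical_smiles(rec.smiles)
        if can is None:  # pre-validated input; guard anyway
            continue
        groups.setdefault(can, []).append(rec)

    samples: list[ModellingSample] = []
    for can in sorted(groups):
        recs = groups[can]
        if policy == "max-sigma":
            chosen = max(recs, key=lambda r: (r.tpacs, -r.wavelength))
        else:
            chosen = min(recs, key=lambda r: abs(r.wavelength - target_wavelength))
        samples.append(
            ModellingSample(
                molecule_id=can,
                smiles=can,
                lg_tpacs=math.log10(chosen.tpacs),
                wavelength=chosen.wavelength,
                solvent=encode_solvent(chosen.solvent, solvent_table),
            )
        )
    return samples


def write_samples(samples: Iterable[ModellingSample], path: str | Path) -> None:
    """Write normalized modelling samples as CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["molecule_id", "smiles", "lg_tpacs", "wavelength",
             "solvent", "et30", "dielectric", "dipole"]
        )
        for s in samples:
            writer.writerow(
                [s.molecule_id, s.smiles, repr(s.lg_tpacs), repr(s.wavelength),
                 s.solvent.name, s.solvent.et30, s.solvent.dielectric,
                 s.solvent.dipole]
            )
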