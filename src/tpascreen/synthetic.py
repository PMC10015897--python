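"""Synthetic chromophore families with planted structure-property laws.

The generator emits homologous series of conjugated molecules whose
log-cross-section follows a stated model,

    lg_tpacs = beta * lg(L) + gamma_da * 1[donor and acceptor present] + eps,

with L the template-predicted conjugation length (in bonds), eps Gaussian
noise in lg units.  Three families are built by SMILES template
concatenation:

* ``polyene``                 H2C=CH-(CH=CH)_{k-1}-H : L = 2k - 1
* ``oligophenylene-vinylene`` m para-linked rings bridged by vinylenes
                              (stilbene at m = 2): L = 6m - 3
* ``donor-acceptor-polyene``  Me2N-(CH=CH)_k-NO2 : L = 2k + 2
                              (dimethylamino donor, nitro acceptor)
* ``donor-polyene``           Me2N-(CH=CH)_k-H : L = 2k
                              (donor-only control; no acceptor, so the
                              push-pull effect is absent)

The donor-only family exists to make the planted effects identifiable: its
conjugation lengths are even, exactly matching the support of the
donor-acceptor family, so a dataset mixing the two decorrelates the D/A
indicator from lg(L) by construction (see :func:`make_recovery_dataset`).

Template arithmetic is verifiable against the conjugation module, which
makes every generated molecule a cross-module oracle.  The generator also
provides a plain linear-Gaussian regression fixture for the selection and
evaluation machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset_io import DEFAULT_DIALECT

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "FAMILIES",
    "family_smiles",
    "make_series",
    "make_recovery_dataset",
    "make_regression_fixture",
]

FAMILIES = (
    "polyene",
    "oligophenylene-vinylene",
    "donor-acceptor-polyene",
    "donor-polyene",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic series.

    ``beta`` is the planted conjugation-length exponent (the literature-
    scale value is about 1.8), ``gamma_da`` the planted donor/acceptor
    boost in lg units, ``sigma_noise`` the lg-unit measurement noise
    (about 0.3 matches the reported reproducibility of experimental
    cross sections).
    """

    family: str = "polyene"
    n_min: int = 2
    n_max: int = 9
    beta: float = 1.8
    gamma_da: float = 0.5
    sigma_noise: float = 0.3
    seed: int = 0
    n_samples: int | None = None  # default: one molecule per repeat count
    methyl_prob: float = 0.0      # per-unit chance of a methyl side group

    def __post_init__(self) -> None:
        if self.family not in FAMILIES and self.family != "mixed":
            raise ValueError(
                f"unknown family {self.family!r}; supported: {FAMILIES + ('mixed',)}"
            )
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.n_max < self.n_min:
            raise ValueError("n_max must be >= n_min")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


def _vinyl_chain(k: int, methyl_mask: tuple[bool, ...] | None) -> str:
    """(CH=CH)_k chain; masked units carry a non-conjugated methyl."""
    if methyl_mask is None:
        return "C=C" * k
    return "".join("C=C(C)" if m else "C=C" for m in methyl_mask)


def _polyene(k: int, mask=None) -> str:
    return _vinyl_chain(k, mask)


def _opv(m: int) -> str:
    if m > 9:
        raise ValueError("oligophenylene-vinylene template supports up to 9 rings")
    smi = f"c{m}ccccc{m}"
    for j in range(m - 1, 0, -1):
        smi = f"c{j}ccc(/C=C/{smi})cc{j}"
    return smi


def _da_polyene(k: int, mask=None) -> str:
    return "CN(C)" + _vinyl_chain(k, mask) + "[N+](=O)[O-]"


def _d_polyene(k: int, mask=None) -> str:
    return "CN(C)" + _vinyl_chain(k, mask)


def family_smiles(
    family: str, k: int, methyl_mask: tuple[bool, ...] | None = None
) -> tuple[str, int, bool]:
    """Template SMILES, predicted conjugation length L, and D/A flag.

    ``methyl_mask`` (vinyl-chain families only) marks repeat units carrying
    a non-conjugated methyl substituent; decoration changes composition but
    never the conjugation length.
    """
    if family == "polyene":
        return _polyene(k, methyl_mask), 2 * k - 1, False
    if family == "oligophenylene-vinylene":
        return _opv(k), 6 * k - 3, False
    if family == "donor-acceptor-polyene":
        return _da_polyene(k, methyl_mask), 2 * k + 2, True
    if family == "donor-polyene":
        return _d_polyene(k, methyl_mask), 2 * k, False
    raise ValueError(f"unknown family {family!r}")


@dataclass
class SyntheticDataset:
    """Generated molecules with planted lg cross sections."""

    config: GeneratorConfig
    df: pd.DataFrame = field(repr=False)

    def write_measurements_csv(self, path) -> None:
        """Emit the dataset in the measurement-table dialect."""
        out = pd.DataFrame(
            {
                DEFAULT_DIALECT["smiles"]: self.df["smiles"],
                DEFAULT_DIALECT["tpacs"]: 10.0 ** self.df["lg_tpacs"],
                DEFAULT_DIALECT["wavelength"]: self.df["wavelength"],
                DEFAULT_DIALECT["solvent"]: self.df["solvent"],
                DEFAULT_DIALECT["method"]: "synthetic",
                DEFAULT_DIALECT["doi"]: "",
            }
        )
        out.to_csv(path, index=False)


def make_series(config: GeneratorConfig) -> SyntheticDataset:
    """Generate one synthetic series under the planted power-law model.

    With ``n_samples`` unset, exactly one molecule per repeat count in
    [n_min, n_max] is produced (a clean homologous series); otherwise
    repeat counts (and, for the mixed family, families) are drawn uniformly
    with replacement, emulating replicate measurements of homologs.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    if config.n_samples is None:
        draws = [(config.family, k) for k in range(config.n_min, config.n_max + 1)]
    else:
        fams = (
            list(FAMILIES)
            if config.family == "mixed"
            else [config.family]
        )
        draws = [
            (
                fams[rng.integers(len(fams))],
                int(rng.integers(config.n_min, config.n_max + 1)),
            )
            for _ in range(config.n_samples)
        ]
    for i, (family, k) in enumerate(draws):
        mask = None
        if config.methyl_prob > 0 and family != "oligophenylene-vinylene":
            mask = tuple(rng.random(k) < config.methyl_prob)
        smiles, true_l, has_da = family_smiles(family, k, mask)
        if Chem.MolFromSmiles(smiles) is None:  # template guard
            raise RuntimeError(f"template produced invalid SMILES: {smiles}")
        lg = (
            config.beta * math.log10(true_l)
            + (config.gamma_da if has_da else 0.0)
            + rng.normal(0.0, config.sigma_noise)
        )
        rows.append(
            {
                "molecule_id": f"{family}-{k}-{i}",
                "smiles": smiles,
                "family": family,
                "repeat_units": k,
                "true_l": true_l,
                "has_da": has_da,
                "lg_tpacs": lg,
                "wavelength": 800.0,
                "solvent": "toluene",
            }
        )
    return SyntheticDataset(config=config, df=pd.DataFrame(rows))


def make_recovery_dataset(
    n_samples: int = 400,
    beta: float = 1.8,
    gamma_da: float = 0.5,
    sigma_noise: float = 0.3,
    methyl_prob: float = 0.4,
    seed: int = 0,
) -> SyntheticDataset:
    """Balanced two-family design for exponent-recovery studies.

    Half the samples are donor-only polyenes (k = 2..9, L = 4..18), half
    donor-acceptor polyenes (k = 1..8, L = 4..18).  The two families share
    the same conjugation-length support, so the donor/acceptor indicator is
    uncorrelated with lg(L) by construction and the planted exponent and
    push-pull boost are separately identifiable.  Random methyl decoration
    (``methyl_prob`` per repeat unit) emulates the scaffold diversity of
    real chromophore data, preventing composition descriptors from acting
    as surrogate length scales.
    """
    n_half = n_samples // 2
    d_only = make_series(
        GeneratorConfig(
            family="donor-polyene", n_min=2, n_max=9, beta=beta,
            gamma_da=gamma_da, sigma_noise=sigma_noise, seed=seed,
            n_samples=n_half, methyl_prob=methyl_prob,
        )
    )
    d_a = make_series(
        GeneratorConfig(
            family="donor-acceptor-polyene", n_min=1, n_max=8, beta=beta,
            gamma_da=gamma_da, sigma_noise=sigma_noise, seed=seed + 1,
            n_samples=n_samples - n_half, methyl_prob=methyl_prob,
        )
    )
    df = pd.concat([d_only.df, d_a.df], ignore_index=True)
    df["molecule_id"] = [f"m{i:04d}" for i in range(len(df))]
    return SyntheticDataset(config=d_only.config, df=df)


def make_regression_fixture(
    n_samples: int,
    n_informative: int,
    n_noise: int,
    coefficients,
    sigma: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standard-normal features with linear Gaussian targets.

    Columns are named x1..x{p}; the first ``n_informative`` carry the given
    coefficients, the rest are pure noise features.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != n_informative:
        raise ValueError("need one coefficient per informative feature")
    p = n_informative + n_noise
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, p))
    y = X[:, :n_informative] @ coefficients + rng.normal(0.0, sigma, n_samples)
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(p)])
    return df, y
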