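"""High-level pipeline runs: from a synthetic or measured table to a fit.

Convenience composition of the stage modules, used by the CLI, the test
suite and reproduction scripts.  Everything here is a plain function call
into the stage modules -- no hidden state.
"""

from __future__ import annotations

from rdkit import Chem

from .dataset_io import ModellingSample, encode_solvent
from .featurization import FeatureMatrix, assemble_matrix, build_catalog
from .interpret import PowerLawFit, fit_power_law, shap_values
from .model_eval import make_regressor
from .selection import forward_stepwise
from .synthetic import SyntheticDataset

__all__ = ["samples_from_synthetic", "featurize_samples", "recover_power_law"]


def samples_from_synthetic(dataset: SyntheticDataset) -> list[ModellingSample]:
    """Turn generated rows into modelling samples (solvent table lookup)."""
    cache: dict[str, object] = {}
    out = []
    for row in dataset.df.itertuples():
        if row.solvent not in cache:
            cache[row.solvent] = encode_solvent(row.solvent)
        out.append(
            ModellingSample(
                molecule_id=row.molecule_id,
                smiles=row.smiles,
                lg_tpacs=row.lg_tpacs,
                wavelength=row.wavelength,
                solvent=cache[row.solvent],  # type: ignore[arg-type]
            )
        )
    return out


def featurize_samples(
    samples: list[ModellingSample],
    radius: int = 4,
    min_support: int = 2,
    include_mff_moe: bool = True,
    blocks: tuple[str, ...] = ("mff", "general", "conjugation", "experimental"),
) -> FeatureMatrix:
    """Catalog build + full matrix assembly for a sample list."""
    mols = [Chem.MolFromSmiles(s.smiles) for s in samples]
    catalog = build_catalog(mols, radius=radius, min_support=min_support)
    return assemble_matrix(
        samples,
        catalog=catalog,
        blocks=blocks,
        include_mff_moe=include_mff_moe,
        moe_properties=("PEOE-Charge", "LogP", "MR"),
        moe_scopes=("all",),
    )


def recover_power_law(
    dataset: SyntheticDataset,
    feature: str = "Conju-Max-Distance",
    selection_runs: int = 8,
    max_corr: float = 0.9,
    seed: int = 0,
) -> tuple[PowerLawFit, list[str]]:
    """Full interpretation pipeline on one dataset.

    featurize -> forward stepwise selection seeded with the conjugation
    length -> fit the reference boosted model on all samples -> exact SHAP
    -> OLS of the feature's attributions on its logarithm.  Returns the
    power-law fit and the selected feature set.

    The interpretation stage works on chemically attributable features
    only: the conjugation, fragment-attributed (MFF-MOE) and experimental
    blocks.  Generic whole-molecule 2D descriptors are excluded here -- they
    duplicate size/composition information in combinations that cannot be
    assigned to substructures, and such near-duplicates of the conjugation
    length would silently split its attribution.  Stepwise additionally
    applies the ``max_corr`` collinearity guard for the same reason.
    """
    samples = samples_from_synthetic(dataset)
    matrix = featurize_samples(
        samples, blocks=("conjugation", "experimental")
    )
    y = dataset.df["lg_tpacs"].to_numpy(dtype=float)

    trace = forward_stepwise(
        matrix.df, y, seed_features=(feature,),
        n_runs=selection_runs, seed=seed, max_corr=max_corr,
    )
    selected = trace.selected
    sub = matrix.df[selected]
    model = make_regressor("xgboost", seed=seed)
    model.fit(sub.to_numpy(dtype=float), y)
    explanation = shap_values(model, sub)
    return fit_power_law(explanation, feature), selected
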