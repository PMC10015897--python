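# Methods

## The modelling problem

Experimental two-photon absorption cross sections σ (in GM) of organic
chromophores span several orders of magnitude, and replicate measurements
of the same dye disagree at the level of ~0.3 in log10 units. All
modelling therefore happens on `lg σ = log10(σ/GM)`: errors of 0.3 lg
units correspond to a factor-of-two accuracy, which is the realistic floor
set by the measurements themselves. A measurement record is (SMILES, σ, λ,
solvent, method, DOI); a modelling sample is one molecule with one selected
record, the solvent encoded by three polarity descriptors — ET(30)
(kcal/mol, betaine-30 scale), static dielectric constant ε, dipole moment μ
(Debye) — and λ kept as a feature, since σ depends strongly on the
excitation wavelength.

### Ingestion rules

* Rows with unparsable SMILES or non-positive σ/λ are dropped and itemized
  in a rejection report; nothing is silently discarded.
* Default filters keep 600 ≤ λ ≤ 1100 nm (sparse data near the boundaries
  is unreliable) and remove molecules containing P, Si or I.
* Multi-wavelength molecules collapse to one sample per canonical SMILES.
  The default policy keeps the record with maximal σ — the peak cross
  section is what screening optimizes — with a nearest-to-target-wavelength
  policy available. Molecule identity is the canonical SMILES of the
  largest covalent fragment.
* The embedded solvent table covers 22 solvents with literature constants
  (Reichardt 1994; CRC Handbook); lookups are case- and alias-insensitive
  and fail loudly with the list of known names.

## Featurization

**Fragment counts (MFF).** Every atom-centered environment of radius
0..4 is exported as a standalone canonical substructure SMILES; the
context beyond the environment is discarded, so identical local fragments
from different molecules collide onto one key. The catalog keeps keys
occurring in ≥ `min_support` molecules (default 2 — singleton fragments
carry no generalizable signal in corpora of a few hundred molecules) in
lexicographic order, making builds byte-reproducible. A molecule's vector
counts catalog-key occurrences. This differs from hashed/folded
fingerprints (no collisions, no linkage context) and is deliberately
simple enough to attribute model behavior to named substructures.

**Atomic attributions and MFF-MOE.** Three atom-attributable properties
are supported, each folded over implicit hydrogens: Gasteiger/PEOE partial
charges (e), Crippen LogP and molar refractivity MR (cm³/mol) atomic
contributions, plus Labute approximate surface area (Å²). For each catalog
fragment instance the attribution is summed over the instance's atoms, and
per molecule the fragment sums are aggregated (max/min/mean/sum; optionally
restricted to fragments inside conjugated systems). `PEOE-Charge-Max`, for
example, is the most positively charged fragment — a marker of conjugated
backbones attached to strong acceptors; `LogP-Min` marks the most polar
(donor/acceptor) fragment; `MR-Max` the most polarizable one.

**General 2D block.** A pinned manifest of 107 standard whole-molecule 2D
descriptors (E-state and partial-charge summaries, VSA bins, connectivity
indices, counts). Pinning by name keeps matrices reproducible across
toolkit upgrades; excluded from the available roster were
fingerprint-density descriptors, eigenvalue-based BCUT2D terms (NaN-prone
on uncommon atom types), the overflow-prone Ipc pair, and redundant mass
variants. Descriptors that fail on a molecule are imputed with the column
median (an all-NaN column becomes 0).

**Conjugation block (21 descriptors).** Conjugated systems are the
connected components of the subgraph of bonds the toolkit flags as
conjugated, plus isolated multiple bonds (kept as "minimal" systems).
Pinned definitions:

* `Conju-Max-Distance` (L): max over systems of the graph diameter in
  bond counts. Butadiene 3, benzene 3, stilbene 9; the polyene homologous
  series increases by exactly 2 per repeat unit.
* `Conju-Branch-Ratio`: fraction of atoms in the largest system with
  within-system degree ≥ 3 (0 for chains and simple rings; 4/19 for the
  triphenylamine core). Dimensionless, in [0,1], and constant along
  homologous chain series — i.e. only weakly tied to L.
* `Conju-Atom-Wt`: molecular weight per heavy atom.
* `Conju-Wt` / `Conju-Stru-VSA` / `Full-Wt`: summed masses (with implicit
  H) and Labute surface contributions over conjugated atoms; total weight.

The remaining descriptors are complementary size/shape/composition
summaries (atom/bond counts, weight and atom fractions, aromatic ring
count, heteroatom content, branch/terminal counts, cyclicity); they are a
reasoned registry, not canonical definitions, and are tagged as such.

**Donor/acceptor assignment.** An editable SMARTS library (amines,
hydroxy/alkoxy, thioether as donors; nitro, cyano, carbonyl, sulfonyl,
pyridinium, benzothiazole as acceptors) is matched against the largest
conjugated system. `DAratio` = (max donor–acceptor shortest-path bond
count within the system) / L — ≈ 1 for dipolar D–π–A rods, ≈ 0.5 for
quadrupolar D–A–D; it is 0 with an undefined flag when either role is
absent. The max-span convention (strongest push–pull axis) is the default;
min is selectable.

**Assembly.** Blocks concatenate in fixed order (MFF | general |
conjugation | [MFF-MOE] | solvent, wavelength) with a provenance tag per
column; duplicate names are an error; the assembled matrix contains no
NaN/Inf.

## Evaluation protocol

240 independent random 85:15 train/test splits (728/128 at the reference
scale of 856 samples; sizes are round(n·0.85) and the remainder), each
seeded by `base_seed + run_index`. Metrics per held-out fold: MSE, MAE, R²
(test-fold variance in the denominator), averaged over runs; the spread of
a sample's held-out predictions across runs doubles as the screening
uncertainty. A failed run is excluded with a warning rather than aborting
the protocol. The regressor registry pins hyperparameters (boosted trees:
500 rounds, learning rate 0.05, depth 6; registry entries for
lasso/elastic-net/random-forest/decision-tree/kNN/AdaBoost/MLP); inside
selection loops a lighter tree configuration (100 rounds, depth 3, lr 0.1)
is used, since selection needs stable rankings, not final-model precision.

## Feature selection

**Combined importance.** Per CV run, three regressors are fitted: LASSO on
z-scored training features (importance = |coefficient|) and the two
boosted-tree flavors (importance = mean |SHAP| on the held-out fold). Each
method's run-averaged vector is normalized to sum 1; the combined index is
their unweighted mean (weights configurable). An all-zero method is
excluded with a warning.

**Backward elimination** removes the lowest-combined-importance feature
one at a time, recomputing importance every `refresh_every` removals
(strict one-at-a-time refresh at 696 features × hundreds of runs is
compute-prohibitive; the refreshed-batch variant preserves behavior at a
fraction of the cost). Ties remove the later column. The trace records
held-out MSE at every size.

**Forward stepwise** starts from a seed set (default: the conjugation
length, the single most informative descriptor) and greedily adds the
candidate with the largest CV-MSE gain until the gain drops below
tolerance. Two stabilizers address a failure mode specific to
*interpretable* selection — near-duplicates of an already-selected feature
can carry marginal signal yet silently split its Shapley credit:

* a collinearity guard (skip candidates with |Pearson r| > `max_corr`,
  default 0.9, to any selected feature), and
* a 1-SE tie-break: among candidates whose CV MSE is within one standard
  error of the best, add the one least correlated with the selected set
  (the parsimony rule familiar from CART/lasso practice).

Both were measured to matter: without them, CV noise admits
length-entangled composition descriptors in roughly half of synthetic
replicates and the recovered power-law exponent scatters by ±0.3.

## Interpretation

**Exact tree Shapley values.** Attributions use the polynomial-time
path-dependent TreeSHAP recursion implemented in-package (numba-compiled
over flat tree arrays) for sklearn tree ensembles, and the xgboost
booster's native exact contributions for xgboost models. Additivity
(base value + Σφ = prediction) holds to ~1e-15 for the float64 in-package
route; xgboost stores leaves in float32, so its additivity holds to ~1e-5.
The implementation is verified against exhaustive-coalition Shapley values
(cover-conditioned expectations, all 2^p subsets) to 1e-9 on small trees.
Non-tree models are rejected; sampling approximations are out of scope.

**Power law.** Because the model lives in lg σ, an OLS fit of φ_L against
lg L has slope = the exponent b of σ ∝ L^b. The fit is unweighted, with
the standard OLS slope error; it requires ≥ 3 distinct abscissae and
positive feature values. Integer-valued features are never jittered for
fitting. The default explains one model fitted on all samples (pooling
across CV models is configurable).

**Add-one-feature refits** analyze features outside the selected set: the
column is appended, the reference model refitted on all samples, and the
new column's attributions read off. **ALE profiles** (first-order,
20 quantile bins, centred to data-weighted mean zero) provide a
SHAP-independent cross-check of a feature's marginal slope; on additive
models the two slopes agree within ~10%.

### Why the interpretation stage restricts the feature pool

The power-law protocol (`pipeline.recover_power_law`) featurizes with the
conjugation, MFF-MOE and experimental blocks only. Generic 2D descriptors
are excluded at this stage by design: several (atom counts, E-state sums,
Kier–Hall terms) are deterministic functions of chain length within a
chemical series, and a tree model will happily route the length effect
through them, which destroys the attribution of the named length feature
without changing predictions. Replacing atom-based descriptors with
fragment-attributed ones for interpretation — and pruning redundant
correlates — is precisely what makes the extracted exponent stable. This
mirrors the two-stage protocol of the interpretability literature: screen
coarsely, then explain a compact model of attributable features.

## Synthetic data: what it emulates, what it does not

The generator builds real molecules (SMILES that parse, featurize and
carry perceivable conjugation) from four templates — polyenes (L = 2k−1),
oligophenylene-vinylenes (L = 6m−3), donor–acceptor polyenes
Me₂N–(CH=CH)k–NO₂ (L = 2k+2) and donor-only polyenes Me₂N–(CH=CH)k–H
(L = 2k) — and plants

    lg σ = β·lg L + γ·1[donor ∧ acceptor] + ε,  ε ~ N(0, σ_noise²).

Defaults: β = 1.8 (the literature-scale conjugation-length exponent),
γ = 0.5 lg units (a realistic push–pull boost), σ_noise = 0.3 lg units
(matching inter-laboratory reproducibility), λ = 800 nm, toluene.
Template L values are cross-validated against the conjugation module on
every generated molecule.

The recovery design (`make_recovery_dataset`, n = 400) mixes donor-only
(k = 2..9) and donor–acceptor (k = 1..8) polyenes, whose L supports are
identical even integers 4..18 — so the D/A indicator is uncorrelated with
lg L *by construction* and β and γ are separately identifiable. Random
methyl decoration of repeat units (probability 0.4, conjugation-neutral)
emulates the scaffold diversity of real data; without it, composition
descriptors are exact within-family length proxies and no attribution
method that conditions on observed splits can keep the length credit where
it belongs.

What passing recovery tests show: the pipeline's featurization, selection
and attribution machinery recovers a planted monotone power law and a
planted group effect from realistic-looking molecule tables at realistic
noise. What they do not show: performance on real measurement
heterogeneity (multiple labs, methods, solvents, wavelength dependence
near resonances), scaffold classes outside the templates, or the
literature exponent itself — those require the deposited experimental
dataset, which is download-gated.

## Numerical choices and degenerate inputs

* lg means log10 throughout.
* Saturated molecules: empty system list, L = 0, branch ratio 0 with a
  degenerate flag, conjugated weight/area 0.
* A molecule with no catalog fragment yields a zero MFF vector and zero
  MFF-MOE aggregates (degenerate flag).
* Gasteiger charges sum to the formal molecular charge within 1e-6
  (conservation is asserted, not assumed); Crippen sums reproduce the
  whole-molecule LogP/MR to 1e-6.
* Split sizes use round-half-up; split RNG is `default_rng(base + run)`.
* Constant features are rejected by ALE; fewer than 3 distinct abscissae
  by the power-law fit.
* All stochastic stages are reproducible from a single base seed.

## Known limitations

* The conjugation-feature registry beyond the seven pinned descriptors is
  a reasoned reconstruction, not canonical.
* The MFF catalog pruning threshold is a free parameter; published
  catalog widths are only reproducible with the original corpus.
* Path-dependent SHAP is used (cover-conditioned expectations);
  interventional SHAP with a background dataset is not implemented.
* xgboost attributions inherit float32 leaf storage (~1e-5 additivity).
* No 3D/conformer descriptors, no quantum-mechanical features, no hashed
  fingerprints — all deliberately out of scope.
* Screening predictions carry ensemble spread as uncertainty; this is a
  stability measure, not a calibrated predictive interval.
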