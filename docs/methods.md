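# Methods

This note documents the model, the numerical conventions, and the design
choices the package makes where the method description leaves the design
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

The package targets binary classification of samples × features real
matrices in the HDLSS regime (features ≫ samples), with class 1 the
positive class. A run is parameterized by an option grid
G = preps × FSS methods × subset sizes × validation methods; each base
classifier ("soldier") draws one *attack vector* from G and executes the
pipeline

1. exclusion of every feature with ≥ 1 missing training value,
2. per-feature scaling fitted on the training set,
3. greedy mutual-information feature selection to the vector's subset size,
4. classifier training.

Soldiers are ranked by the efficiency index ρ = MCC × accuracy computed
from pooled out-of-fold training predictions under the vector's own
validation method. Filtering keeps MCC > 0 and ρ > ε; ensembles are built
by greedy non-deteriorating majority-vote addition in decreasing ρ. The
two phases differ only in their classifier registries: phase 1 (LIG) uses
parameter-free families at library defaults, phase 2 (FT) grid-searches a
parameter space per soldier and keeps the assignment with the best
selection ρ (ties: higher MCC, then first seen in deterministic grid
order).

### What the ρ-dominance guarantee does and does not say

Greedy non-deterioration makes the ρ trajectory non-decreasing and the
ensemble's *selection* ρ ≥ the best member's selection ρ; with the default
rebuild-from-scratch final strategy this extends to every filtered soldier
of both phases. These are construction guarantees on the data ρ is
optimized against (out-of-fold training predictions by default). Nothing
forces them to transfer to an external validation set, and runs exist where
a phase ensemble beats the final ensemble on holdout; the pipeline asserts
the selection-side guarantees on every run and reports holdout metrics
without any such claim.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `preps` | none, quantile, robust, standard | scaling methods; "none" covers the impute-only configuration so the grid keeps its 4×6×3×2 = 144 arity |
| `subset_sizes` | 10…250 | FSS sizes of the reference configuration |
| `grid_fraction` | 0.5 | per-phase random sample of G, without replacement |
| `selection_fraction` | 0.33 | ε is set so at least the top third of eligible soldiers pass; boundary ties are admitted ("at least") |
| `epsilon_lig` / `epsilon_ft` | unset | explicit ε overrides, bypassing the fraction rule |
| `n_bins` | 5 | equal-frequency bins for MI estimation; standard for small-sample plug-in MI |
| `final_strategy` | c | a = pool both phase ensembles; b = extend the lower-ρ phase ensemble; c = re-rank the union and rebuild |
| `strict_improvement` | false | false keeps ρ-ties during greedy addition (literal "did not deteriorate"); true trades ensemble size for strict gains |
| `selection_on` | cv | "holdout" re-scores selection on validation predictions for comparison runs; leaks the holdout into model selection and is not the default |
| `max_features` | 5000 | guard refusing feature counts whose FSS would run for days; `--force` overrides |

FT grids default to the published tuning spaces (MLP: 3 learning-rate
schedules × 8 alphas × 3 activations × 1–3 hidden layers of width 100;
SVM: 5 C × 4 gamma × rbf/linear; random forest: 5 sizes × 2 criteria ×
bootstrap on/off). The MLP hidden-layer specification is read as *k*
hidden layers of width 100, k ∈ {1,2,3}.

## Numerical conventions

- **MCC**: any zero factor in the denominator ⇒ MCC = 0 (degenerate
  confusion table). This is the standard convention and makes the
  "MCC > 0" eligibility rule well defined for constant predictors.
- **ε from a fraction**: k = ⌈fraction · n⌉; all members tied with the
  k-th ρ pass; the reported ε is the smallest passing ρ minus 2⁻⁴⁰ so the
  strict test ρ > ε reproduces the pass set.
- **Scalers**: standard (x−mean)/sd, robust (x−median)/IQR, quantile
  empirical CDF with averaged ranks, (rank−0.5)/n. Zero sd/IQR ⇒ the
  feature transforms to exactly 0 (0.5 under quantile); constant features
  are kept, not dropped, so column indices stay aligned across attack
  vectors. Quantile values outside the training range clip to 0/1. All
  three maps are monotone per feature.
- **Scaling/FSS fitting scope**: fitted once per attack vector on the whole
  training set, not refit inside CV folds; only the classifier is refit per
  fold. This follows the pipeline order of the method description and keeps
  one selection per soldier, at the cost of mild optimism in out-of-fold
  scores (feature selection has seen the fold's labels). The permutation
  null in the test suite bounds this optimism at the tested sizes.
- **Discretization**: equal-frequency by rank, bin = ⌊rank · n_bins / n⌋
  with minimum ranks for ties, so equal values always share a bin and a
  constant feature is a single bin.
- **MI estimation**: plug-in estimator on the observed contingency table,
  natural log, clamped at 0 against negative rounding. Joint variables use
  the product alphabet of the two bin codes.
- **Greedy tie-breaks**: criterion scores within 10⁻¹⁰ of the step maximum
  are treated as tied and resolved to the lower feature index — identical
  contingency tables can produce sums a few ulp apart depending on
  summation order.
- **Vote ties**: an even split is decided by the member with the highest
  selection ρ, deterministically.
- **Stratified 10-fold CV** is reduced to min(10, smallest class count)
  folds when a class has fewer than 10 samples; LOOCV is unchanged.
- **Seeding**: every stochastic component (grid sampling per phase,
  classifier randomness per soldier, random grid search) draws a sub-seed
  derived from the master seed and a context key via `SeedSequence`, so
  runs are bit-reproducible end to end.

## Synthetic data

The generator emulates the statistical shape of small two-class expression
cohorts: its defaults are 70 training / 88 validation samples with a 26/70
positive fraction, 500 features with 10 informative (class-mean shift =
`effect_size` within-class SDs, default 2.0), 10 redundant (a source
informative feature plus N(0, 0.2) noise), the rest N(0, 1) noise, and a
5% missing rate confined to a random half of the noise features. Missing
values are kept out of planted features by default so that the exclusion
rule cannot silently delete the signal a recovery test is looking for; a
`missing_anywhere` flag exists to stress the exclusion rule itself.

What the generator does *not* emulate: platform-specific intensity
distributions, probe effects, batch structure, heavy tails, or correlated
noise blocks. Tests passing on this generator therefore demonstrate the
correctness and the construction properties of the method, not expected
performance on any real cohort.

## Problem sizes used by the test suite

The suite exercises the method at desk scale: oracle-equivalence of the
FSS criteria on 50 random 30×8 datasets; planted-feature recovery at
n = 100 × 500 features over 50 seeds per criterion; construction
guarantees over 100 seeded runs at n = 60 × 200 features with one attack
vector, three LIG soldiers and one 2-point-grid FT soldier; and the
end-to-end reference-cohort shape (70/88, 26/44 split) with a minimal
configuration. The full default grid (144 vectors × 3 + 3 families, full
FT grids) is the production configuration and is exercised for
construction, not exhaustively in CI-scale tests.

## Known limitations

- Binary classification only; no multi-class MCC generalization.
- Hard-label majority voting only — no probability averaging, weighted
  votes or stacking.
- The selection protocol reuses whole-training FSS (see above); a
  fold-nested variant is not implemented.
- ε-filtering assumes ρ values are comparable across soldiers, which holds
  only when they share the selection protocol; mixing `selection_on`
  modes within a run is not supported.
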