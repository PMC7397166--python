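# ito — two-phase heterogeneous ensembles for expression classification

`ito` builds binary classifiers for high-dimension, low-sample-size
(HDLSS) gene-expression data — the regime of microarray and bulk/single-cell
transcriptomic cohorts where a few dozen samples carry tens of thousands of
features. In this regime single tuned models overfit easily, and accuracy
alone is a misleading score on imbalanced cohorts. The package implements an
infiltration-tactics optimization (ITO) scheme: a *two-phase heterogeneous
ensemble* in which a quick first wave of parameter-free classifiers
establishes a reliable baseline, and a slower wave of grid-tuned classifiers
then refines it — with the baseline model usable the whole time the tuned
phase is still training.

## The method

Every base classifier (a *soldier*) is assigned an **attack vector**, one
4-tuple from the Cartesian grid

G = preprocessing × FSS method × subset size × validation method

with preprocessing ∈ {none, quantile, robust, standard}, feature-subset
selection ∈ {mRMR, JMI, JMIM} (greedy mutual-information filters on
equal-frequency-discretized features), subset size ∈ {10, 50, 100, 150, 200,
250} and validation ∈ {stratified 10-fold CV, LOOCV}. A random half of G is
sampled per phase.

Each soldier is scored by pooled out-of-fold predictions on the training set
under its own validation method, using the **efficiency index**

ρ = MCC × accuracy,

the product of the Matthews correlation coefficient and the classification
accuracy. MCC is robust to class imbalance; the product penalizes models
that buy accuracy with unreliability (or vice versa). Soldiers with
MCC ≤ 0 are discarded; a threshold ε (chosen so that at least the top 33%
pass, or set explicitly) filters in the "successful" members, i.e. ρ > ε.

**Phase 1 (LIG)** trains parameter-free classifiers (decision tree,
AdaBoost, extremely randomized trees) and combines the successful ones into
a majority-vote ensemble by *greedy non-deteriorating addition*: candidates
are visited in decreasing ρ; one that lowers the ensemble's ρ is discarded.
The trajectory of ρ across accepted additions is therefore non-decreasing,
and the ensemble's selection-ρ is at least that of its best member.

**Phase 2 (FT)** trains parameterized classifiers (random forest, SVM, MLP)
with an exhaustive or randomized grid search per soldier, keeping the
parameter assignment with the best selection ρ. The final ensemble is then
rebuilt from scratch over the union of filtered LIG and FT soldiers, ranked
by ρ (strategy *c*; the weaker pooling strategies *a* and *b* are also
implemented for comparison). By construction the final ensemble's
selection-ρ dominates every individual soldier's.

A seeded synthetic-data generator produces HDLSS two-class datasets with
planted informative, redundant and noise features, class imbalance and
missing values, so the entire method is exercisable without downloading any
cohort.

## Worked example

Simulate a cohort shaped like a small toxicogenomics study (70 training /
88 validation samples, 26 of 70 positive, 500 features of which 10
informative + 10 redundant, class shift 2 SD), then run a minimal
configuration:

```bash
cat > sim.yaml <<EOF
effect_size: 2.0
seed: 7
EOF
ito simulate --spec sim.yaml --out sim/
ito run --train sim/train.tsv --valid sim/valid.tsv --config cfg.yaml --out run/
```

with `cfg.yaml` selecting one attack vector (standard scaling, mRMR,
10 features, 10-fold CV), two LIG families and a 2-point random-forest FT
grid. The run prints

```
final ensemble: accuracy=0.9773 mcc=0.9521 rho=0.9304
```

and `run/summary.tsv` holds the validation metrics of every entity:

```
entity           accuracy        mcc             rho
lig_member_best  0.977272727273  0.952067617629  0.930429717228
ft_member_best   0.988636363636  0.975900072949  0.964810299392
lig_ensemble     0.977272727273  0.952067617629  0.930429717228
ft_ensemble      0.988636363636  0.975900072949  0.964810299392
combined         0.977272727273  0.952067617629  0.930429717228
final            0.977272727273  0.952067617629  0.930429717228
```

Reading: on this draw the tuned forest is the strongest single soldier
(validation MCC 0.976); the two-phase ensemble matches the LIG baseline at
MCC 0.952 and accuracy 0.977. The greedy guarantee (final ρ ≥ every
soldier's ρ) holds on the *selection* protocol it optimizes — out-of-fold
training predictions — and, as here, transfers to unseen data only
approximately. `run/lig_ensemble.json` is written before FT training
starts, and `run/improvements.tsv` gives the percentage gain
100·(final − baseline)/final of the final ensemble over each column.

The same run is available programmatically:

```python
from ito import RunConfig, SyntheticSpec, generate, run_ito
train, valid, truth = generate(SyntheticSpec(effect_size=2.0, seed=7))
report = run_ito(train, valid, RunConfig(seed=7))
```

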