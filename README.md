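# bayescart

Bayesian classification by averaging over decision trees sampled with
reversible-jump MCMC, with posterior feature importance and weak-feature
ensemble refinement — built around the problem of assessing newborn brain
maturity from two-channel sleep EEG.

## The problem

The postconceptional age (PCA) of a healthy newborn normally matches the
age an expert would estimate from the sleep EEG; a mismatch of two or more
weeks flags possibly abnormal brain development. Automating that
assessment turns it into an ordinal classification task: given spectral
features of a recording made via the central-temporal derivations C3-T3
and C4-T4, predict the age group (e.g. six classes for 40–45 completed
weeks). Clinically useful answers need more than a point prediction —
they need the full class posterior, including its uncertainty.

## The method

**Feature space.** Each recording is Fourier-transformed over 10 s epochs
into the six standard bands — Subdelta (0–1.5 Hz), Delta (1.5–3.5),
Theta (3.5–7.5), Alpha (7.5–13.5), Beta1 (13.5–19.5), Beta2 (19.5–25) —
and summarised by absolute and relative band powers and their variances,
for each channel and the channels' sum: 6 × {abs, rel} × {C3-T3, C4-T4,
sum} powers plus the matching variances = **72 features**.

**Model.** A classification tree θ with split parameters
(s_pos, s_var, s_rule) and k leaves; each leaf carries a
Dirichlet(1,…,1) prior over the C class probabilities, giving the
marginal likelihood ∏_leaves Γ(C) ∏_c Γ(n_jc+1) / Γ(n_j+C) and leaf
predictions (n_jc+1)/(n_j+C). The predictive distribution integrates
over trees,

    p(y | x, D) = ∫ p(y | x, θ, D) p(θ | D) dθ ≈ (1/N) Σ_i p(y | x, θ⁽ⁱ⁾, D),

approximated by averaging over N trees sampled from the posterior with a
reversible-jump chain using four moves — birth, death, change-split,
change-rule — under uniform priors on the splitting feature and its
observed values, a leaf-size floor (pruning factor, default 6), and
Metropolis-Hastings-Green acceptance.

**Refinement.** The fraction of split nodes testing each feature across
the ensemble is its posterior usage frequency. Features used with
frequency below a threshold T are *weak*; discarding every tree that
splits on a weak feature sharpens the ensemble — raising accuracy and
lowering predictive entropy — without re-running the sampler.

## Worked example

```python
import bayescart as bc
from sklearn.model_selection import train_test_split

table = bc.generate_table(bc.TableSpec(seed=11))   # 6 classes x 100, 72 features
X, y = bc.split_xy(table)
X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=1/3,
                                          stratify=y, random_state=0)
clf = bc.BayesianTreeClassifier(burn_in=5_000, post_burn_in=2_000,
                                thin=7, random_state=1).fit(X_tr, y_tr)
```

On this synthetic six-class table (first 10 of 72 features informative,
effect size 1.5 within-class SDs between adjacent ages) the run prints:

```
trees collected : 285
acceptance rate : 0.494
max usage freq  : 0.058
accuracy +/-0w  : 38.0%
accuracy +/-1w  : 83.0%
accuracy +/-2w  : 97.5%
entropy         : 438.7 bits
T=0.005         : 33 weak features, 103/285 trees kept
refined accuracy: 38.5%, entropy 434.4 bits
```

Reading this: the chain kept every 7th of 2,000 post-burn-in states
(285 trees); usage frequencies top out near 0.06, so most of the 72
features are rarely used; exact-match accuracy is 38% (chance is 16.7%)
and rises steeply under the ±1/±2-week tolerances appropriate to ordinal
age classes; refining at T = 0.005 removes the trees touching the 33
rarely-used features — keeping 103 of 285 trees — and nudges accuracy up
while lowering the total predictive entropy (uncertainty) on the test
set.

The same workflow is scriptable from the shell:

```bash
bayescart simulate table --classes 6 --per-class 100 --seed 1 -o table.csv
bayescart sample --data table.csv --burn-in 5000 --post-burn-in 2000 -o ens.json
bayescart refine --ensemble ens.json --threshold 0.003 -o refined.json --report usage.csv
bayescart sweep --data table.csv --thresholds 0:0.001:0.005 -o table1.csv
```

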