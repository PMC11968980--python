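# grexcontact

Enhancer RNAs (eRNAs) are short, mostly bidirectional transcripts produced
at active enhancers. Like canonical genes, their expression is partly under
cis-genetic control, so a per-transcript elastic-net model of expression on
nearby genotypes yields a *genetically regulated expression* (GReX)
component that can be imputed into any genotyped cohort. `grexcontact`
implements an analysis pipeline built around one question: **does the GReX
of an enhancer–gene pair predict how often the two elements touch in 3D
(Hi-C contact frequency)?** — together with the association-layer
bookkeeping that surrounds that question (TWAS significance thresholds,
GWAS-locus classification, Mendelian-randomization tallies, eQTL-set
comparison, colocalization accounting).

The package is aimed at statistical/regulatory genomicists who want a
tested, self-contained implementation of each step, runnable end to end on
synthetic data with known ground truth.

## What it computes

**Expression models (`grex`).** For each transcript, residualize expression
on covariates, then fit an elastic net (mixing α = 0.5, penalty by inner
5-fold CV) on cis dosages within ±1 Mb of the TSS. Nested CV gives an
out-of-fold cv R² = sign(r)·r² with its correlation-test p; a model is
*imputable* when cv R² > 0 and p < 0.05. GReX = Xw. A vectorized
single-variant cis scan with Benjamini–Hochberg FDR provides eQTL sets.

**Pair assembly (`contact_pairs`).** Binned contacts (text cooler-dump,
BEDPE or dense, 10 kb default) are stored upper-triangular, balanced with
iterative correction (ICE) until row sums equalize, intersected with
annotations (half-open, ≥1 bp), and turned into rows
`(grex_up, grex_down, pair class, distance, contact)` for every bin pair
with contact ≥ 1 whose transcripts are {eRNA, eRNA} or {eRNA, gene}.

**Contact models (`contact_models`).** A linear baseline plus polynomial /
random-forest / SVR / gradient-boosting grids, and a NumPy feed-forward
network trained by mini-batch gradient descent on

MSE = (1/n) Σᵢ (Yᵢ − Ŷᵢ)²,  scored by R² = 1 − Σᵢ(Ŷᵢ−Yᵢ)² / Σᵢ(Yᵢ−Ȳ)².

Named presets reproduce the three published optimal architectures
(whole blood 2×120 hard-sigmoid / NAdam lr 0.01; cerebellum 2×90 softsign
/ Adagrad lr 0.3; K562 run-on 2×150 ReLU / Adagrad lr 0.2).

**Evaluation (`evaluation`).** Per-pair relative error E = |ŷ − y| / y,
exact two-feature Shapley attribution via the four-coalition closed form,
cross-tissue transfer R², and distance–contact Pearson correlations.

**Bookkeeping (`downstream`).** Bonferroni thresholds (α/n_tests, further
divided by n_traits for phenome-wide scans), locus labels
(eRNA-only/gene-only/both/neither), causal fractions, peak-overlap
fractions, Jaccard and nearest-TSS eQTL comparisons, and the
colocalization rule PP ≥ 0.7 in ≥ 1 tissue with its exclusive/shared
identities.

**Synthetic data (`synthetic_data`).** Generates genotypes, annotations
(eRNA median length ≈ 550 bp, >90% under 2 kb), expression with known
heritability, and contact matrices with exponential distance decay plus a
planted smooth non-linear GReX link — plus all plain-text fixture formats.

## Worked example

```python
from dataclasses import replace
import grexcontact as gc

# 20,000 synthetic pairs: contact = 4 + 3·softsign(g_up)·softsign(g_down) + noise
ds, noiseless = gc.planted_link_dataset(20_000, seed=1)
train, test = gc.split_train_test(ds, 0.8, seed=1)

arch, cfg = gc.PRESETS["cerebellum"]          # 2×90 softsign, Adagrad lr 0.3
model = gc.train_nn(train, arch, cfg)
print(f"test R2        = {gc.evaluate_r2((test.contact, model.predict(test))):.3f}")
print(f"noise ceiling  = {noiseless.var() / ds.contact.var():.3f}")

rep = gc.shap_two_feature(model, train)
print(f"SHAP up/down   = {rep.contribution_up_pct:.2f}% / {rep.contribution_down_pct:.2f}%")

spec = gc.bonferroni_thresholds(0.05, 40_749)  # eRNA-tissue TWAS pairs
print(f"TWAS threshold = {spec.display}")
```

Output:

```
test R2        = 0.367
noise ceiling  = 0.383
SHAP up/down   = 50.06% / 49.94%
TWAS threshold = 1.23e-06
```

The network recovers nearly all the explainable variance (0.367 of a 0.383
ceiling set by the injected noise); because the planted link is a pure
interaction, an ordinary linear regression on the same two features scores
R² ≈ 0. The Shapley split is ~50/50 here because the synthetic link is
symmetric in its arguments. The threshold is 0.05/40,749 Bonferroni
correction across eRNA-tissue pairs.

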