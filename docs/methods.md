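# Methods

## The model

The pipeline treats outcome prediction as supervised regression from a
17-component treatment description to 26 bone-healing outcome measures.
All networks use logistic-sigmoid units throughout, including the
output layer; outcome targets are min-max scaled to [0, 1] per column
so bounded sigmoid outputs are well-matched to the targets. The
candidate set comprises 16 types: feedforward networks with 0, 1, 2,
3, 5, 7 or 10 hidden layers of 100 units, and a recurrent network
whose 100-unit hidden population is fully recurrently connected, each
variant with or without a 50-unit autoencoder layer between input and
the first hidden layer.

**Loss and masking.** Most source studies report only a subset of the
26 outcomes, so each outcome cell carries an observation mask and the
training loss is the masked half-SSE over observed cells only
(`E = ½ Σ_{k∈observed}(t_k − o_k)²`). Masked cells contribute zero
error and zero gradient. A zero-fill view of the outcome matrix exists
for dense display, but masked loss is the default: zero-filling would
teach the network that "unreported" means "zero", which is false for
positive-scaled outcomes. RMS error (training, held-out, everywhere)
is likewise computed over observed cells only.

**Learning rules.** Plain SGD: gradients are averaged over
`batch_size` consecutive presentations per update, and the training
budget counts presentations (one pattern shown once), not updates.
Presentations are drawn uniformly at random with replacement from the
training set (a fixed-shuffle epoch mode exists as an option). The
depth-0 network's update is the delta rule, realised as the same
backpropagation code path specialised to no hidden layers (verified
against the textbook formula in the tests). No momentum, weight decay
or adaptive optimizers — generalization is controlled only by the
fixed presentation budget and architecture choice.

**Recurrent dynamics.** The hidden circuit state settles by synchronous
iteration `s ← σ(W_in·x + W_rec·s + b)` from `s = 0.5`, to max-norm
tolerance 1e-8 within 500 steps (non-convergence raises). Gradients
use the fixed-point adjoint iteration
`u ← σ′(z*) ⊙ (g + u·W_recᵀ)` at the settled state, iterated to the
same tolerance — the classical recurrent-backpropagation reading of
"backpropagation through a settled circuit". At the default
initialisation (below) the effective Jacobian has spectral radius well
under 1, so both iterations contract. Analytic gradients for all 16
types match central finite differences to better than 1e-6 relative
error (typically 1e-8–1e-10).

**Initialisation.** Weights uniform on ±1/√fan-in (fan-in = inputs +
circuit size for recurrent hidden units), biases zero, deterministic
per seed. This keeps sigmoids unsaturated and the recurrent map
contractive at the start of training.

**Autoencoder pretraining.** For "+ae" types, a 17→50→17
reconstruction network is trained by the same SGD on the training
inputs (training split only during generalization assessment, so no
information about held-out patterns leaks through the encoder); its
input→hidden half is installed as the encoder and is excluded from
every subsequent gradient update (bit-identical before/after training,
enforced by test).

## Protocol

**Scaling.** Per-column min-max to [0, 1] for inputs and outputs,
fitted on observed entries of the training portion only; constant
columns are flagged degenerate and scale to 0. Values falling outside
a reused record's range (e.g. held-out patterns, screened
combinations) are clipped to [0, 1] with a logged warning. The map is
invertible on non-degenerate columns to 1e-9.

**Generalization assessment.** Per repeat: a fresh seeded random split
(175 train / 50 test at full scale; proportional for smaller
datasets), scaling refitted on the training portion, fresh
initialisation, fixed-budget training, RMS on the held-out split. The
mean over repeats (10 at full scale) is the selection criterion;
architecture ties break toward fewer parameters.

**Hyperparameters.** Learning rate and batch size are swept
independently — the rate over a log grid at a fixed default batch
size, then the batch size at the winning rate — because the two do not
interact over this protocol; this costs |lr| + |batch| − 1 evaluations
instead of the full product (a full-grid mode exists for
verification). Default grids: 10 log-spaced rates in [1e-3, 1], batch
sizes {1, 2, 4, 8, 16, 32, 64, 128, 175}.

**Ensemble.** The selected type is retrained on the full dataset as an
ensemble of independently seeded members (10 at full scale); screening
averages the members' output activations arithmetically. Because each
member's outputs and the composite score are related by per-column
affine maps, scoring on scaled or unscaled ensemble means is exactly
equivalent under min-max normalization (tested property).

**Screen.** The 9 screened factors take quantized levels — BMP2
{0, 5, 10, 15} mg, BMP7 {0, 5} mg, OG {0, 50, 100, 150} µg, PDGF
{0, 50, 100, 150, 200} µg, PU {0, 50, 100, 150} days, ES/BMAC/PRP
{0, 1}, EBG {1}. Interior dose levels not fixed by the published
extremes (BMP2 5/10, OG 50/100) are evenly spaced; the feasible count
(2400) is invariant to that choice. Feasibility removes combinations
where PU and ES are both active, or BMAC and PRP are both active —
encoded as "not both nonzero", which reproduces the 2400 count
exactly. Enumeration is lexicographic in the factor order above with
ascending levels, making downstream ranking deterministic; ranking
ties keep enumeration order. Each combination is embedded into the
17-dim input by name with the 8 context inputs at zero.

**Efficacy.** Twelve outcomes count as higher-is-better (DR, BF3, BF6,
MV/TV, PLF-FR, ODI, FR, FH, OW, RO, HO, IS) and five as
lower-is-better (TWB/CH, TRU, RBG, NH, DY; the remaining nine are
excluded). Each selected outcome is min-max normalized **across the
screened combination set** (not the training data — both options are
available), lower-is-better columns are flipped as 1 − normalized, and
the 17 values averaged. Degenerate (zero-range) columns score 0 with a
log message. "TWC/CH", an alternate spelling of TWB/CH, is accepted as
a column alias. Pearson correlations over the top-k combinations use
the two-sided t approximation `t = r·√((n−2)/(1−r²))` with n−2 df;
constant factors (EBG) are reported as not-applicable; the default
report filters at p < 0.05 with no multiplicity correction (a
Bonferroni option exists). Values are reported to 4 decimal places.

## The synthetic generator

The curated literature table itself cannot be redistributed with this
package, so `synthetic.reference_dataset()` provides a synthetic
stand-in and, more importantly, a **known ground truth** for
validating the pipeline. The planted model is

    y_k(x) = base_k + Σ_i M[i,k]·x_i + Σ_(i,j,k,c) c·x_i·x_j + ε,
    ε ~ N(0, noise_sd),

with coefficients chosen so that a shared "healing quality" latent —
strongly increased by BMP2, BMP7 and OG, mildly decreased by PDGF,
modestly increased by ES/BMAC/PU — drives every outcome, positively
for the higher-is-better outcomes and negatively for the
lower-is-better ones. The default design plants a BMP2×BMP7 synergy on
fusion-related outcomes and an OG×PDGF trade-off, echoing the
qualitative correlation structure the screen is meant to expose.

Emulated features of the real table: ~75% of rows contain exactly one
active non-vehicle agent (single-agent literature dominates); the
vehicle EBG is present in every row; factor levels are drawn from the
same quantized level sets the screen uses (so train and screen
supports align); outcomes sit on heterogeneous positive scales
spanning 2–277; each outcome is independently reported with
probability 0.6 (masked otherwise, at least one observed per row);
additive Gaussian noise with sd 2.0 on the raw outcome scale
(moderate: 1–20% of a column's span depending on the outcome). The
packaged 225-row stand-in additionally clips observed values into
[2, 277] and anchors the extreme cells to exactly 2 and 277, matching
the published display range of the original table.

Not emulated — and therefore not validated by passing tests:
study-level heterogeneity (the same intervention reported differently
by different labs), correlated outcome noise, publication bias,
between-study unit drift, or any real pharmacology. Recovery results
on synthetic data show the *pipeline* works when its assumptions hold,
not that the biological predictions are correct.

`planted_efficacy_scores` applies the noiseless planted map to
embedded combinations and then the identical flip/normalize/average
rule, giving the ground-truth ranking used in recovery tests.

## Experiment scales and design choices

Desk-scale defaults keep the full test suite around two minutes while
exercising the full-scale code paths; the `paper` pipeline profile
encodes the full protocol (50,000 presentations, 10 repeats, 10
members, all 16 types, 175/50 splits).

- *Linear-recovery check*: noiseless synergy-free data, n = 200,
  depth-0 network, 5,000 presentations, 3 repeats → mean held-out RMS
  ≈ 0.02.
- *Logistic floor*: a sigmoid output unit cannot represent an affine
  target exactly, so even noiseless additive data leaves a residual
  training RMS of ≈ 0.02 at convergence; learnability thresholds are
  therefore set at 0.05, not at the noise floor of a linear-output
  model.
- *Additive control*: comparisons between depths on additive data use
  a budget (15,000 presentations) long enough for every candidate to
  be near convergence — in an under-trained regime such a comparison
  measures optimisation speed rather than representational need.
- *Interaction detection*: 400 patterns with 50% single-agent rows,
  4×-strength BMP2×BMP7 synergy, noise sd 0.5, 40,000 presentations —
  enough co-occurrence rows (~30) and training for hidden layers to
  learn the product term; multilayer types then beat depth-0 on
  held-out RMS in ≥ 4/5 master seeds.
- *Ranking recovery*: 3-member ensemble of the
  autoencoder + two-hidden-layer type, 20,000 presentations on the
  default 225-pattern dataset, scored over all 2400 combinations →
  Spearman ≈ 0.99 against the planted ranking.

Numerical conventions collected in one place: settling and adjoint
tolerance 1e-8 (max 500 steps); scaling invertibility 1e-9; gradient
oracle 1e-6 relative (central differences, h = 1e-6); efficacy
normalization attains exact 0/1 endpoints per column; ranking ties →
enumeration order; architecture ties → fewer parameters; all derived
seeds are SeedSequence children masked below 2³¹.

## Known limitations

- The efficacy score is relative to the screened set: adding or
  removing combinations changes every score (not just new rows), which
  is inherent to min-max normalization across the screen.
- With a single scalar `noise_sd` on heterogeneously scaled outcomes,
  relative noise differs across outcomes by design; per-outcome noise
  would need a vector extension.
- The recurrent type is substantially slower to train than the
  feedforward types (settling per presentation) and was not the
  selected architecture in any experiment here; it is exercised mainly
  by the gradient and settling tests.
- Training uses full batch-size semantics on a Python loop over
  updates; at full scale (50,000 presentations, batch 1) a single
  training run takes on the order of a minute per network on one CPU.
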