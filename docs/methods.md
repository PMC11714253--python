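# Methods

## Factor-graph representation

The metabolic map is a directed bipartite factor graph: reaction modules
(factors) connect to the metabolites they consume and produce.  Metabolites
are *intermediate* when they have at least one producing and one consuming
module — these carry per-sample flux-balance constraints — and *end*
otherwise (boundary sources and sinks, exempt from balance).  Compartments
(cytosol, mitochondrion, extracellular) are encoded by duplicating species
per compartment in the network tables; the compartment label is metadata and
does not enter the balance computation.  Metabolite kind is taken from an
explicit table when provided and otherwise inferred from the
producer/consumer pattern.

The bundled network (`fluxcyte/data/central_metabolism_modules.tsv`) is a
curated reconstruction assembled for this package from public pathway
knowledge: glycolysis, the upper and lower TCA cycle, glutaminolysis,
glutamine/glutamate metabolism, glutathione metabolism, and three minor
branches (nucleotide synthesis, serine synthesis, aspartate–malate shuttle),
totalling 31 modules, 16 intermediate and 15 end metabolites, and 253
distinct human gene symbols.  It is a synthetic stand-in with the documented
structure, not a copy of any externally curated table; gene-to-module
assignments follow standard pathway databases (e.g., HK1/HK2 with glucose
uptake, GCLC/GCLM/GSS in the glutamate-to-glutathione module M27, GLUD1/
GLUD2 in the glutamate-to-2-oxoglutarate module M28).

## Flux model

Each module m has an independent function mapping its gene expression in
sample j to a scalar flux.  The function is a fully connected network with
one hidden tanh layer of `max(4, ceil(n_genes/2))` units (configurable), a
linear output, **plus a direct linear skip path from the inputs to the
output**; the predicted flux is the absolute value of this output.  The skip
path is load-bearing: in joint training the tanh units of individual modules
can saturate and freeze that module's output at a constant, and the linear
path keeps a gradient route open.  The absolute-value output keeps
predictions non-negative regardless of the penalty weight; the explicit
non-negativity penalty remains in the objective and is reported (it is zero
under this parametrization).  Modules none of whose genes are measured are
modeled as free per-sample scalars, still constrained by balance and scale
terms; their prediction on unseen samples falls back to the fitted mean.

Inputs are log1p-transformed and min-max scaled per gene over the training
samples (the raw FPKM-like dynamic range destabilizes small networks).  The
total-activity anchor TA_j is computed on the raw scale as the sum of
expression over the network's gene universe.

The objective is the sum over samples of squared in/out imbalance at every
intermediate metabolite, plus `alpha * sum(|Flux| - Flux)` (alpha = 1) and
`beta * sum_j (sum_m Flux_mj - TA_j)^2` (beta = 0.1).  A third configured
weight, gamma = 1, is stored for configuration fidelity but enters no term
of the objective; it is deliberately inert.  Since only the TA anchor sets
an absolute scale, fluxes are relative and downstream analyses use them
through correlations only.

Training is full-batch Adam, learning rate 0.02 for 2000 epochs by default;
all parameters are initialized from a seed (per-module seed streams), the
output bias starts at `mean(TA)/n_modules` so initial fluxes sit at the
right order of magnitude, and the best-loss parameter state is restored
after the last epoch, so the final loss never exceeds the initial one.
These defaults were chosen from training-dynamics checks on the
glutamine-like toy problem: shorter schedules (e.g., 100 epochs at rate
0.008) leave the balance residual at ~20% of the flux scale and the branch
modules unrecovered, while 2000 epochs cost about two seconds at 100 samples
and six modules.  Non-finite losses abort with the offending epoch and term.
Identical (input, config, seed) gives bit-identical results; everything is
deterministic numpy.

`FluxEstimator` follows the scikit-learn estimator protocol (fit/predict,
`get_params`/`set_params`, trailing-underscore fitted attributes, samples as
rows) and composes with sklearn tooling; `fit_flux`/`predict_flux` wrap it
for the gene-by-sample file convention.

## Cytotoxicity statistic

Signature scores are the mean log1p expression over the present markers of a
set; the CD8+ T-cell abundance set is CD3E, CD2, CD3G, CD3D, SIRPG, CD6,
TIGIT and the cytotoxicity set is CD8A, SLA2, NKG7, PRF1, GZMA, GZMH.
Relative cytotoxicity is their ratio, with abundances below 1e-8 yielding an
undefined (excluded) value rather than a division blow-up.  This scorer is a
deliberately simple stand-in for a full deconvolution-based estimate of
cell-type abundance: it is monotone and rank-stable, and the downstream
analyses (grouping, correlation ranking) consume it only through ranks.  One
mathematical caveat is documented and tested: mean-of-log1p is exactly
rank-invariant under global rescaling only for single-marker sets; for
multi-marker sets the per-gene log compression differs and invariance is
approximate (empirically Spearman > 0.95 under a 7x scale change).

## Correlation ranking

Per cohort, the Pearson coefficient between each feature (gene expression or
module flux) and relative cytotoxicity is computed on pairwise-complete
observations; constant vectors or fewer than three pairs give a missing
value, logged rather than raised.  The cross-cohort average is the plain
unweighted mean over cohorts with a defined coefficient, and features are
ranked by average in increasing order (most negative first), ties broken
lexicographically.  No multiple-testing machinery is attached: the ranking
is by coefficient, not p-value.

## Synthetic data

The generator is the deliberate inverse of the model: the model maps genes
to flux, the generator maps known fluxes to genes, so recovery tests are not
circular.  Balanced ground-truth fluxes draw source-module fluxes from
LogNormal(log 20, 0.4) per sample and propagate them through the module DAG,
splitting each intermediate's inflow among its consumers by per-sample
Dirichlet(2, ..., 2) proportions; every intermediate balances exactly (to
float round-off).  Only acyclic graphs in which each module consumes at most
one intermediate are supported by this propagation; the bundled 31-module
network (whose citrate synthase consumes two intermediates) is used for
structural tests, not for balanced simulation.  Expression for each module
gene is `w * Flux^e * exp(N(0, noise_sd^2))` with per-gene weight
LogNormal(0, 0.25) and exponent uniform in [0.5, 1.5], plus 200 background
genes with log-normal expression so gene matching and the TA restriction are
exercised.  Default study conditions: the glutamine-like six-module graph,
100 samples, noise_sd 0.2.

Immune-structured cohorts add latent per-sample T-cell abundance
(LogNormal(1, 0.5)) and relative cytotoxicity (LogNormal(0, 0.5)); T-cell
markers respond proportionally to abundance, cytotoxic and effector markers
(GZMA, TNF, IFNG, PRF1) to abundance times relative cytotoxicity, each with
20% multiplicative noise.  The glutathione-arm flux is drawn as a decreasing
function of the cytotoxicity z-score (log-slope -0.8) while the
2-oxoglutarate-arm flux is independent of it; the branch parent is their sum,
so balance holds exactly and only one arm is coupled.  A planted metabolic
gene decreases linearly in the cytotoxicity z-score (`max(4 - effect_size *
z, 0.1)` times 10% noise): the linear response keeps the anti-correlation
strong on the raw expression scale where Pearson is computed — a steeply
exponential response would be so right-skewed that its raw-scale coefficient
weakens below the flux-driven module genes.  All randomness flows from one
spec seed through named substreams (flux, weights, noise, immune, markers),
so stages reproduce in isolation.

What passing tests on these cohorts do *not* show: the generator has no
batch effects, no tumor-purity variation, no realistic gene-gene
correlation structure beyond the planted couplings, and no dropout; results
on real cohorts depend on properties the simulation does not model, and
gene rankings obtained from real CRC cohorts are not reproduced here — they
require the external cohort data and a full deconvolution algorithm in place
of the signature scorer.

## Numerical choices and degenerate inputs

Gene symbols are matched case-insensitively after trimming; duplicate genes
within a module are de-duplicated with a warning.  Expression must be
non-negative and finite; constant genes min-max scale to zero.  Grouping by
a gene's expression uses floor(n * fraction) group sizes with ties resolved
by stable sample order.  Conservation assertions use a 1e-9 absolute
tolerance; loss-term oracle comparisons use 1e-12.  The negative-flux
fraction tolerance (1%) is enforced after fitting; under the absolute-value
parametrization it is trivially met, and predictions are never clipped.

## Known limitations

- Flux identifiability is only up to the information in the gene inputs and
  the balance/anchor constraints; branch splits with uninformative gene
  expression are under-determined.
- The cytotoxicity scorer is validated at the rank level only and is not a
  substitute for deconvolution when absolute cell fractions matter.
- The balanced-flux generator does not support cycles through intermediates
  or multi-intermediate-substrate modules.
- Training is full-batch and desk-scale; no GPU path and no single-cell
  specific handling (the intended inputs are bulk cohort matrices).
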