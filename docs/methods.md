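# Methods

This note records the statistical model behind each stage, the
parameter choices that matter, and the places where the design was
genuinely open and a decision had to be made.

## Concentration handling and PQN

Spectrometer output in mmol/L is converted to tissue concentration as
`c · V · M / m` (mmol/L × mL = μmol; μmol × g/mol = μg; divided by the
dry insoluble pellet mass in mg), so all downstream statistics operate
on μg per mg pellet.

Probabilistic quotient normalization estimates one dilution factor per
sample as the median of that sample's per-metabolite quotients against
a reference profile, and divides the sample by it. The reference
profile (default policy `all-samples`) is the element-wise median
across samples *after scaling each sample by its own median*. Scaling
first makes the reference shape invariant to per-sample dilution,
which gives the implementation two exact properties (machine
precision, tested to 1e-10):

- **idempotence** — `pqn(pqn(X)) = pqn(X)`;
- **dilution removal** — `pqn(D·X) = pqn(X)` for any positive
  per-sample diagonal scaling `D`.

These two properties are jointly incompatible with unit preservation:
a table of identical rows and its uniformly rescaled copy lie on the
same dilution orbit, so any normalization with exact dilution removal
must map them to the same output. The implementation therefore
expresses concentrations *relative to the reference profile* — a table
of identical samples maps to itself divided by its common median. The
classical form that preserves raw units (reference = plain element-wise
median) is neither idempotent nor exactly dilution-invariant; users who
need a fixed external reference can pass an explicit profile, which
reproduces textbook behaviour (a sample equal to 3× the reference gets
factor 3 exactly).

Samples whose quotient set is degenerate (all-zero rows) are rejected
by name rather than silently propagated.

## Univariate screening

Each metabolite is tested per ordered group comparison with the
Mann–Whitney U test: the exact permutation distribution (two-sided p =
doubled minimum tail, capped at 1) when the pooled sample size is ≤ 12
with no ties, and the tie-corrected normal approximation otherwise.
Group sizes of 8–12 animals, as in the emulated study, therefore
always use the approximation, while the exact branch serves small
fixtures; the exact branch is verified against full enumeration of all
C(n₁+n₂, n₁) labelings in the tests. p-values are deliberately *not*
adjusted for multiple testing: the screen is exploratory, effect sizes
are mild, and a type II error is considered costlier than a false
positive. Fold changes are log₂ ratios of arithmetic group means; a
zero denominator mean leaves the fold change missing with a warning
while the p-value is still reported.

PCA is computed on column-autoscaled data (centred, unit variance):
concentrations span roughly four decades, so unscaled components would
be dominated by the most abundant compounds (glucose, taurine).
Constant metabolites are dropped with a warning before scaling.
Explained-variance fractions are taken against the total variance, so
they are comparable across choices of retained components.

## Correlation patterns

Pearson r with the t-distributed two-sided p (df = n−2) is computed
per pair per experimental group; groups need at least 4 samples. A
pair enters a comparison only when p < α (strict, default 0.05) in
*both* groups — no multiplicity correction, matching the screening
philosophy. On top of this dual-significance filter:

- **opposite_under_treatment**: opposite r signs between disease and
  treated, *and* absent from the wildtype–disease dual-significant
  set. "Absent" is operationalized as failing dual significance there,
  because that matrix only displays dual-significant pairs.
- **corrected_toward_wildtype**: opposite signs between wildtype and
  disease, dual-significant in the disease–treated comparison, with
  the treated sign equal to the wildtype sign.

The classes are disjoint by construction. Two caveats are inherent to
the definitions: the filter is sensitive to outlier samples (no
outlier rule is applied, as none is defined for the emulated study),
and the absence clause of the opposite class rests on a *negative*
significance statement — a truly null wildtype correlation is still
spuriously significant with probability α, so even at large n about
5% of genuinely treatment-specific pairs will be dropped or
reclassified per dataset. The generator-recovery tests exhibit exactly
this ceiling (typically 17–20 of 20 seeds with perfect recovery at
n = 500 per group).

## Metabolic model and path finding

The model dialect (documented in `model.py`) carries metabolites with
formulas, synonyms and compartments; reactions with signed
stoichiometry, reversibility, transporter flags, gene associations and
an explicit *half-reaction partition*; a cofactor-couple registry; and
a hub list. Half-reaction partitions are model **data**: the chemical
knowledge of which sub-couples transfer electrons, amino or phosphate
groups cannot be recovered from stoichiometry alone. A fallback
heuristic (pair registered cofactor couples first, group the remainder
as the main couple) handles undeclared reactions with a warning.

Within a half-reaction, substrate s links product p iff both carry
carbon (parsed from the formula) and neither is a hub, or (s, p) is a
registered cofactor couple. Hubs (water, protons, SAM and similar
currency species) are never linkable; redox couples such as NAD⁺/NADH
belong in the cofactor registry, not the hub list (the loader rejects
hub-listed cofactor members). Pair weights are 1 except for transporter
reactions and half-reactions producing a *uniquely produced*
metabolite, which weigh 0. "Uniquely produced" is read model-wide: a
metabolite appearing as forward product of exactly one reaction. This
is an interpretation — a per-subsystem reading is also defensible —
and it makes weight-0 steps common in very small models, which is why
the toy generator defaults to a denser topology (12 reactions over 8
core metabolites).

Paths between two metabolites are all simple chains of pair steps with
total weight in {1, 2}: zero-weight steps do not count toward the cost
but at most two may occur consecutively (transporters chain at most
cytosol ↔ organelle ↔ extracellular). Irreversible reactions are
traversed forward only; chaining on compartment-qualified ids makes
compartment compatibility implicit. The path finder is verified
against an independent brute-force enumerator on randomized toy
models.

The assembled network holds measured metabolites, declared bridge
metabolites (unmeasured glycolysis/TCA intermediates that prevent
gaps), reporter-selected metabolites, and the genes of every reaction
on a retained path; connected components with at most two significant
members (genes and metabolites counted together) are dropped whole.
Export is node-link JSON plus GraphML (list/dict attributes are
JSON-encoded to strings for GraphML's scalar-only schema).

## Reporter scoring

Ratios are distinct unordered substrate–product pairs; a ratio's gene
set is the union over all reactions contributing the pair, and
gene-less ratios (e.g. diffusion transporters) are excluded with a log
entry. Weights: start at 1, divide by the ratio's gene count, then
divide each gene's weights by that gene's maximum — so every gene has
weight exactly 1 somewhere and promiscuous ratios (ATP/ADP-like) do
not dominate. The statistic `X_i = −Σ w_ij ln p_j` uses the natural
logarithm (Fisher convention) on rank-transformed p-values
(`rank/(N+1)`, average ranks on ties), computed over **all** genes in
the supplied table — including unmapped transcripts — because the
transform's resolution is set by the table size; restricting it to
network-mapped genes would floor the transformed values at ~1/(m+1)
for m mapped genes and destroy power in small models.

The null is simulated per ratio: `X* = −Σ w_ij ln U_j` with i.i.d.
Uniform(0,1) draws (justified because the rank transform makes the
marginal null uniform; resampling observed transformed values is a
reasonable alternative but is not the default), N = 100 000 by default,
upper tail, with the add-one estimator `p̂ = (#{X* ≥ x} + 1)/(N + 1)`
so p̂ ∈ [1/(N+1), 1]. The test is one-sided (X grows with evidence).
With equal weights and k genes the null is exactly ½·χ²(2k), which the
tests use as a closed-form check. Each ratio's RNG stream is keyed on
(seed, ratio id), so results are independent of scoring order.

## DE gene selection

Selected = {FDR < 0.05} ∪ {|log₂FC| > 0.5}, partitioned by fold-change
sign (zero-fold-change selections are reported separately, never
assigned a direction). The union reading of the combined rule is the
one under which the emulated study's printed totals reconcile:
81 FDR-significant genes plus the fold-change-only genes give 184
overall. Pass `lfc_cut=None` for the pure FDR selection.

## Synthetic data

The generator's defaults are the emulated study conditions: about ten
samples per group, baseline concentrations log-uniform over two
decades (tissue NMR panels span ~0.003–12 μg/mg), multiplicative
log-normal noise with CV 0.2, group effects as multiplicative mean
shifts. Correlation patterns are implanted through shared latent
factors with group-specific loading signs (log-scale loadings of ±0.3
give pair correlations of ~0.7, the strength of the reported
patterns); latent factors guarantee a positive-definite covariance and
exact per-group sign control, which direct covariance matrices would
not. Gene statistics draw signal genes from Beta(a, 1) (default
a = 0.1; a = 1 is the uniform null), null genes — including 200
background genes emulating the unmapped transcriptome bulk — from
Uniform(0,1), with |log₂FC| increasing in evidence and
Benjamini–Hochberg FDR computed from the p column. Model topology,
concentrations and gene statistics use independently seeded
sub-streams, so changing one stage's draw does not perturb the others.

What the generator does **not** emulate: NMR spectral overlap and
deconvolution error, count-based expression noise, batch effects,
outlier animals, or realistic pathway topology. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
its stated model, not robustness to the failure modes of real data.

## Problem sizes and numerical choices

The test and acceptance suites run the reporter calibration at 200
ratios × 20 seeds with 2 000 null draws per ratio, recovery at 5
signal among 195 null ratios with 5 000 draws, pattern recovery at 500
samples per group over 20 seeds, and the path-finder oracle over 50
random models of at most 30 reactions — sizes chosen so the whole
suite completes in seconds while keeping Monte-Carlo standard errors
small against the tested tolerances (statistical checks use 3 MC
standard errors). Printed-table fixtures are asserted exactly. Ties in
ranks use average ranks; equality boundaries follow the strict
inequalities of the definitions (p < α, |log₂FC| > cut); degenerate
inputs (all-zero samples, constant metabolites, empty reaction sides,
unknown references) raise or warn explicitly rather than propagating.

## Known limitations

- The long-treatment printed table is stored exactly as printed, and
  its marks disagree with the surrounding text (32 starred vs "31",
  11 hash marks vs "12"); the discrepancy is preserved, not resolved.
- The opposite-pattern class inherits the α-level ceiling described
  above; exact-recovery-across-seeds statements are capped near
  (1−α)^k for k implanted opposite pairs.
- Small models make zero-weight (uniquely-produced) steps pervasive;
  interpretation of "uniquely produced" is model-wide and documented
  as such.
- PQN output is expressed relative to the reference profile (see
  above); absolute-unit workflows should pass an explicit reference.
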