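# Methods

## Scope and data model

The package analyses per-sherd lipid-residue tables: lipid yield (µg g⁻¹),
relative abundances of a closed vocabulary of diagnostic compounds, and
δ¹³C (‰ VPDB) of up to three fatty-acid proxies — palmitic (C16:0),
stearic (C18:0) and oleic (C18:1) acid. Absent measurements stay absent
throughout; nothing is silently coerced to zero. δ¹³C values outside
[−45, 0] ‰ are rejected at parse time as unit errors. When a table carries
no per-measurement analytical uncertainty, a default sd of 0.3 ‰ is
assumed (typical GC-C-IRMS replicate precision); it is a config knob.

## Biomarker screening

The aquatic flag requires *both* the C18 and C20 APAA homologues, or
dihydroxy acids alone. The conjunctive APAA reading is deliberate: C18
APAAs alone also form from heated terrestrial plant oils, so counting them
would inflate aquatic frequencies; a config switch restores the disjunctive
reading. Aquatic sherds are subtyped by two closed windows — %SRR of
phytanic acid in [20, 47] % and TMTD/phytanic in [0.34, 1.63] — seeded from
observed shellfish ranges; they are descriptive screening windows, not
validated decision thresholds, and both are configurable. The maize alkanol
flag requires C32 *n*-alkanol above a configurable trace threshold plus at
least two supporting even-carbon alkanols in C28–C36, because trace
dotriacontanol is common in non-maize residues. Ratio denominators of zero
yield absent values, never infinities. Site summaries count only sherds
strictly above the lipid-yield threshold (default 5 µg g⁻¹): lower yields
are too close to blank levels for reliable interpretation.

## Confidence-ellipse classification

A reference class in (δ¹³C₁₆:₀, δ¹³C₁₈:₀) space is summarised by its sample
mean and unbiased covariance, and its "68 % confidence ellipse" is the
*population-coverage* contour: squared Mahalanobis radius equal to the
χ²(2 df) quantile at the level. A standard-error-of-the-mean ellipse would
shrink with reference sample size and be useless for classifying individual
sherds, which is the task here. Membership is boundary-inclusive and
multi-label: overlapping reference classes are a fact of the isotope space
and are reported, not resolved by a nearest-class rule. An optional
additive correction (default 0 ‰) can shift modern reference values for
the fossil-fuel depletion of atmospheric δ¹³C before comparison with
archaeological samples.

## Mixing model

Fractions f (Σf = 1, fatty-acid basis) generate each proxy j as the
concentration-weighted mean δ_j(f) = Σᵢ fᵢc_ijδ_ij / Σᵢ fᵢc_ij. Source
signatures δ_ij ~ N(δ̄_ij, σ²_ij) marginalise analytically because δ_j(f)
is linear in them given f: proxy j is Gaussian with mean Σᵢ w_ij δ̄_ij and
variance Σᵢ w²_ij σ²_ij + σ²_obs,j + σ²_model, where
w_ij = fᵢc_ij / Σₖ fₖc_kj. If a full per-source signature covariance is
supplied, the proxies are jointly Gaussian with the induced cross-proxy
covariance; the default is per-proxy diagonal uncertainty. The model-error
term σ_model (default 0.5 ‰) absorbs cooking and burial fractionation the
model does not represent; setting it to zero recovers the pure
analytical-uncertainty model. Concentrations are treated as fixed
constants in % of total fatty acids.

The prior on f is flat Dirichlet(1) — no informative dietary prior is
imposed. Two independent routes compute the posterior:

- **Grid oracle** — exhaustive evaluation on a regular simplex lattice
  (default step 0.05; refused above four sources). Lattice masses are
  normalised posterior weights; their means are quadrature estimates of the
  posterior means.
- **Metropolis sampler** — random-walk Metropolis on additive-log-ratio
  coordinates z (f = softmax(z, 0)) with the log-Jacobian Σ log fᵢ in the
  target. Four chains from dispersed N(0, 2) starts; during burn-in the
  isotropic proposal scale is multiplicatively adapted every 50 iterations
  toward ≈30 % acceptance and then frozen; all post-burn-in draws are
  retained (no thinning). Split-R̂ and effective sample size are computed
  per source; a run is flagged non-converged when any R̂ > 1.05, and
  non-identifiable when every posterior sd is within 10 % of the
  Beta(1, S−1) prior sd.

Sherds lacking δ¹³C₁₈:₁ are modelled on the two saturated-acid proxies;
sherds with a single proxy are screened and classified but not inverted.
Weight-basis conversion is the explicit final step wᵢ ∝ fᵢ/φᵢ with φᵢ the
fatty-acid mass fraction per unit dry tissue, so lean sources (maize
kernels, φ = 0.04 in the default table) gain share relative to fat-rich
ones (ruminant adipose, φ = 0.60).

With the default maize/ruminant fixtures the Δ¹³C₁₈:₀₋₁₆:₀ mixing curve is
not monotone over the whole simplex edge: it falls from the pure-ruminant
value to an interior minimum near f_maize ≈ 0.8–0.9 (where maize finally
dominates even the C18:0 pool) and rises again toward pure maize. The
diagnostic claim — adding C3 animal fat to maize, or maize to C3 fat,
drives Δ below both pure-source values — holds on both monotone branches
and is what the tests assert.

## Statistics

Mann–Whitney U is computed from midranks; the reported statistic is
min(U_x, U_y) by default (a "which U was published" ambiguity; U_x is
available by config). The two-sided p-value is exact via the standard
counting recurrence when n₁·n₂ ≤ 400 with no ties, otherwise a
tie-corrected normal approximation with continuity correction. Pearson's r
uses df = n − 2 and the t transform; incomplete pairs are dropped and the
retained n reported. The two-sample t test is Welch by default; a
zero-variance mean shift returns an overflow-safe capped statistic rather
than infinity, and zero variance with equal means is an error. scipy's
implementations serve only as independent cross-checks in the test suite.

## Synthetic-data generator

Each scenario draws per-sherd compositions from a Dirichlet law (or a fixed
f), draws source signatures from their uncertainty law per sherd, mixes
them through the forward model, adds Gaussian analytical noise (0.3 ‰
default) and drops δ¹³C₁₈:₁ with probability 0.3. Biomarker presences are
Bernoulli draws conditioned on the true composition — aquatic markers with
probability 0.02 + 0.5·f_marine, maize alkanols with 0.02 + 0.4·f_maize —
conditionally independent of the isotope noise given f, the simplest law
consistent with using both evidence strands jointly. The two presets mirror
the study design in size and lean: a marine/C3-leaning tradition of 55
sherds and a maize-leaning tradition of 154 sherds, whose mean simulated
Δ¹³C₁₈:₀₋₁₆:₀ is correspondingly less and more negative. The generator does
not emulate chromatographic artefacts, degradation kinetics or burial
alteration, so passing tests demonstrate correctness of the inference
chain under the stated generating law, not robustness to those real-data
effects.

The shipped source table (`data/synthetic_sources.csv`) is a synthetic
stand-in with plausible-range signatures and concentrations for the four
food groups; real applications should substitute measured reference fats
in the same dialect. Real per-sherd measurement tables, once available,
drop in at `data/supplementary/S1_sherds.csv` for the reproduction entry
point `sherdmix.pipeline.reproduce_published_contrasts`.

## Problem sizes and numerical choices

Default MCMC settings are 4 chains × (2000 burn-in + 4000 retained)
iterations, ample for 3–4 source problems (typical ESS in the thousands).
The oracle-agreement check uses grid step 0.02 and 4 × 12 500 retained
draws; credible-interval calibration uses 100 replicates at 4 × 1500 draws,
which keeps the full validation in the low minutes on one core while
holding Monte-Carlo error well below the 0.02 comparison tolerance.
Ellipse-coverage checks use 10⁵ draws (binomial se ≈ 0.0015 at level 0.68).
Degenerate inputs fail loudly: fewer than three or collinear reference
points, singular covariances, zero-concentration proxies and empty samples
raise typed errors rather than propagating NaNs.

## Known limitations

Each sherd is modelled independently; there is no hierarchical pooling
across sherds or sites. Concentrations carry no uncertainty. The
FRUITS-style covariance semantics of the original modelling environment
are under-specified publicly; the diagonal-plus-optional-covariance
formulation here is the package's own explicit choice. Biomarker screening
is qualitative by design — %SRR and TMTD ratios are not converted into
quantitative shellfish contributions.
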