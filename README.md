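# sherdmix

Screening, classification and Bayesian source mixing for lipid residues
extracted from archaeological pottery.

Organic residues absorbed in pottery walls preserve the fatty acids of the
foods once cooked in the vessels. Three strands of evidence identify those
foods:

1. **Biomarkers** — ω-(o-alkylphenyl)alkanoic acids (APAAs, thermal products
   of unsaturated fatty acids whose C20 homologues indicate aquatic oils),
   dihydroxy acids, isoprenoid fatty acids (TMTD, pristanic, phytanic acid,
   with the %SRR diastereomer ratio of phytanic acid and the TMTD/phytanic
   ratio separating shellfish from fish/marine mammals), long-chain
   *n*-alkanols (C32, *n*-dotriacontanol, a maize marker), lauric acid (palm
   oil) and bacteriohopanes (putative fermentation markers).
2. **Compound-specific carbon isotopes** — δ¹³C of palmitic (C16:0) and
   stearic (C18:0) acid, the offset Δ¹³C₁₈:₀₋₁₆:₀ = δ¹³C₁₈:₀ − δ¹³C₁₆:₀, and
   classification against reference-fat classes drawn as 68 % confidence
   ellipses in (δ¹³C₁₆:₀, δ¹³C₁₈:₀) space.
3. **A concentration-dependent Bayesian mixing model** over up to three
   proxies (δ¹³C of C16:0, C18:0 and oleic acid C18:1), estimating the
   fractions *f* of maize, marine, C3 plant and ruminant sources in a
   vessel's fatty-acid pool.

The mixing model's forward prediction for proxy *j* is the
concentration-weighted mean

δ_j(f) = Σᵢ fᵢ·c_ij·δ_ij / Σᵢ fᵢ·c_ij,

with c_ij the concentration of fatty acid *j* in source *i* (% of total
fatty acids). Because maize kernel oil is ¹³C-enriched (C4 photosynthesis),
rich in C16:0 and nearly devoid of C18:0, mixing maize with C3 animal fats
drives Δ¹³C₁₈:₀₋₁₆:₀ strongly negative — an isotopic fingerprint of maize
processing that does not require preserved maize biomarkers. Source
signatures are Gaussian and marginalise analytically; the posterior over
*f* (flat Dirichlet prior) is sampled by random-walk Metropolis in
additive-log-ratio coordinates and cross-checked against an exhaustive
simplex-lattice oracle. Fatty-acid-basis fractions convert to dry-tissue
weight fractions by wᵢ ∝ fᵢ/φᵢ, with φᵢ the source's fatty-acid content per
unit dry tissue.

Because the per-sherd measurements behind the original study are not
publicly accessioned, the package ships a seeded synthetic-assemblage
generator with known ground truth (plus a synthetic stand-in source table),
so every stage is testable end to end.

## Worked example

```python
import sherdmix as sm

sources = sm.default_sources()          # maize, marine, C3_plant, ruminant
by = {s.source_name: s for s in sources}

# the maize fingerprint: Δ13C_18:0-16:0 along the maize→ruminant mixture
curve = sm.mixing_curve(by["maize"], by["ruminant"], 100)
print(curve["delta_18_0_16_0"].min())   # -7.26 ‰, far below both endpoints
                                        # (-2.00 ‰ pure ruminant, -1.50 ‰ pure maize)

# invert a three-proxy observation for its source composition
observed = {"C16:0": (-22.0, 0.3), "C18:0": (-28.0, 0.3), "C18:1": (-24.0, 0.3)}
post = sm.run_mcmc(sources, observed, sm.PipelineConfig(seed=1))
print(post.summary_table().round(2))
```

The posterior table reports, per source, the mean, sd, 2.5/50/97.5
percentiles of its fraction of total fatty acids, plus split-R̂ and
effective sample size. For a maize-dominated synthetic sherd
(`analysis/04_bayesian_mixing.py`) the pipeline prints, e.g.:

```
guarani_like-0042: maize 87 % of fatty acids [77, 95] → 96 % by dry-tissue weight (converged=True)
```

i.e. maize supplies 87 % of the fatty-acid pool (95 % credible interval
77–95 %) and, because maize kernels are lean, an even larger share — 96 % —
of the dry tissue processed.

The numbered scripts under `analysis/` run the full narrative on the
synthetic assemblages: simulation (01), biomarker screening (02), isotope
classification and the mixing-curve prediction (03), Bayesian mixing with
the grid-oracle check (04), and the between-group statistics (05), writing
their tables under `results/`. The same workflow is available as a console
tool: `sherdmix simulate|screen|classify|mix|stats|all`.

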