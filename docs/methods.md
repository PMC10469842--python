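# Methods

## The estimation problem

Quantitative stable-isotope probing (qSIP) infers, taxon by taxon, how much of a
heavy-isotope tracer (here ¹³C or ¹⁵N from labeled fungal necromass) a microbial
population incorporated into its DNA. Incorporation makes DNA denser; in a CsCl
equilibrium gradient each taxon's DNA bands at a buoyant density set jointly by
its GC content and by its isotopic composition. Comparing where a taxon bands in
a labeled sample versus an unlabeled control converts a density shift into an
**atom fraction excess (AFE)** — the fraction of the element's atoms in the
taxon's DNA that are the heavy isotope, beyond natural abundance.

## Estimation chain

For each taxon *i* and sample, with fractions *f* at measured densities
*x_f*, within-fraction relative read abundance *p_if*, and fraction DNA
concentration *D_f*:

1. **Weighted abundance** `y_if = p_if · D_f`. Weighting by total fraction DNA
   turns compositional amplicon reads into a quantity proportional to the
   taxon's DNA mass per fraction. Replicate concentration measurements, when
   present, are averaged per fraction first.
2. **Weighted average density (WAD)** `W_i = Σ_f x_f y_if / Σ_f y_if`.
3. **GC content** from the unlabeled WAD via Schildkraut's relation,
   `GC_i = (W_light,i − 1.66) / 0.098`. Noisy WADs can imply GC outside [0, 1];
   such values are clamped and flagged rather than discarded.
4. **Molecular weights**: mean nucleotide weight of unlabeled DNA
   `M_light = 0.496·GC + 307.691` g/mol, and the fully heavy weight
   `M_heavymax = M_light + 9.974564 − 0.4987282·GC` (¹³C) or
   `M_light + 3.517396 + 0.5024851·GC` (¹⁵N).
5. **Labeled weight** from the proportional density shift,
   `M_lab = M_light · (W_lab / W_light)`.
6. **AFE** `A_i = (M_lab − M_light)/(M_heavymax − M_light) · (1 − a)`, with
   natural abundance `a` = 0.01111233 (¹³C) or 0.003663 (¹⁵N).
7. **Normalization and retention**: AFE is capped at 0.99, the maximum possible
   given 99 %-enriched growth media (a hard cap; sub-cap values are not
   rescaled, negatives are kept but never called enriched), and a taxon is
   called enriched when its normalized AFE strictly exceeds 0.10.

The constants in steps 3–6 are the standard qSIP calibration for dsDNA in CsCl;
all are overridable through `IsotopeConstants.with_options`.

### Design choices

- **Single-pair design.** The study being emulated pooled field replicates,
  leaving one labeled and one unlabeled sample per condition, so no per-taxon
  bootstrap confidence interval is computed; enrichment is called solely by the
  0.10 threshold. The threshold is interpreted as 0.10 absolute atom fraction
  excess (10 percentage points), not 0.10 × 0.99; both are configurable.
- **Missing taxa.** A taxon with zero weighted abundance in either member of a
  pair has no defined WAD there; it is skipped with a logged reason rather than
  imputed. Zero-read fractions contribute `y_f = 0`.
- **Density axes.** Labeled and unlabeled gradients keep their own measured
  fraction densities; nothing is interpolated across gradients.

## Synthetic gradient forward model

The simulator provides ground truth for every downstream stage. Each taxon's
DNA bands as a Gaussian centred on its expected buoyant density — the exact
inverse of the chain above, `expected_wad(GC, A)` — with a common standard
deviation `band_sigma` (default 0.006 g/mL, diffusion-dominated banding, no GC
heterogeneity within a taxon). The gradient spans 1.665–1.784 g/mL, cut into
24 equal raw fractions and composited into 9 equal-width density bins
(half-open, last closed). A composite's measured density is the DNA-mass-
weighted mean of its member raw-fraction densities; its read counts are a
multinomial draw across taxa proportional to DNA mass (default 20 000
reads/fraction, comparable to the rarefaction depths used downstream); its DNA
concentration is the simulated mass over a 40 µL resuspension volume with
lognormal measurement error (CV 10 %).

The full study generator emits 12 samples — {low, high} melanin × {¹³C, ¹⁵N,
unlabeled} × {earlier, later} — over one community (default 200 bacterial +
100 fungal taxa, GC uniform on [0.3, 0.7], lognormal abundances). True AFE is
Beta-distributed, scaled to [0, 0.99], with condition-dependent means (¹³C:
0.35 low / 0.20 high melanin; ¹⁵N: 0.30 / 0.18; both attenuated ×0.7 at the
later stage) so that the low-melanin and earlier-stage contrasts have the
directionality the analysis is meant to detect. A taxon's ¹³C and ¹⁵N AFE are
coupled through a Gaussian copula (ρ = 0.7), and a taxon assimilates C with
probability 0.95 and N with probability 0.70, producing a non-trivial
C/N/co-enrichment partition. These defaults are plausible for an enriched
decomposer community, not fitted to any dataset.

### What the simulator does and does not emulate

It reproduces the features the estimator is sensitive to: banding geometry,
compositional sequencing at finite depth, DNA-concentration weighting and its
measurement error, and paired labeled/unlabeled design. It does **not** emulate
PCR/primer bias, chimeras or OTU-clustering artifacts, GC heterogeneity within
genomes, gradient-to-gradient density calibration drift, or ecological
covariance between abundance and enrichment. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated noise model,
not robustness to every artifact of real amplicon data.

### Numerical behaviour worth knowing

- `atom_fraction_excess(expected_wad(gc, A)) = A` to 1e-10: the closed-form
  chain and its inverse are exact.
- A single taxon fractionated noiselessly round-trips through banding,
  compositing and estimation to ≤ 1e-6, provided its band stays ≥ 5σ inside
  the collected density window; mass banding outside the window is lost, so
  taxa near the edges are biased low by truncation.
- With a shared multi-taxon gradient, each composite fraction reports one
  community-mass-weighted density, while each taxon's mass within the bin has
  its own centroid. This discretization contributes an AFE error of order 0.01
  with 9 bins — comparable to, and at high read depth larger than, the
  multinomial counting noise. Under the default recovery conditions (100 taxa,
  10⁵ reads/fraction, 9 fractions) the median absolute AFE error is ≈ 0.016.

## Enrichment statistics

- **Partition**: a taxon is C-enriched (N-enriched) if retained in at least one
  ¹³C (¹⁵N) comparison; counts and nearest-integer percentages of the enriched
  union are reported per domain.
- **Co-enrichment regression**: AFE-N on AFE-C for co-enriched taxa by
  standardized major axis (SMA) regression — the type II method of choice when
  both variables carry comparable error on different scales: slope =
  sign(r)·sd(y)/sd(x) through the centroid (major-axis regression would be the
  alternative; SMA is the default here). The slope CI is a percentile bootstrap
  over 1 000 case resamples with a fixed seed. When r = 0 exactly the slope
  sign convention is positive.
- **Slope-recovery simulations** place latent points exactly on a line and add
  independent Gaussian noise (sd 0.05) to both axes; the latent slope is
  pre-corrected so the *population* sd(y)/sd(x) — hence the population SMA
  slope — equals the requested value exactly.
- **Community contrasts**: OLS of AFE on two binary indicators (low melanin,
  later stage) with t tests per coefficient and a directionality report.
- **Rarefaction**: multivariate hypergeometric subsampling (without
  replacement) to fixed depths (defaults 20 000 bacterial / 11 000 fungal
  reads); samples below depth are excluded with a warning.

## Necromass chemistry calculator

Sequential forage-fiber (ANKOM) analysis partitions necromass into a
cell-soluble fraction (neutral-detergent loss) and a non-hydrolyzable residue
(after 72 % H₂SO₄). Given the initial tissue's %C and %N and a fraction's
recovery of initial C and N, the fraction's C:N is
`(fracC% · initC%)/(fracN% · initN%)`; the calculator works on printed rounded
values — no back-solving of unrounded masses, since the packaged composition
table rests on a single measured sample per necromass type — so recomputed
ratios can deviate from tabulated ones by the rounding, up to ~3 % relative
(the low-melanin rows show ~1–2 %).

## Problem sizes and determinism

The default end-to-end run is 300 taxa × 12 samples × 9 fractions with 20 000
reads/fraction and completes in seconds; recovery and slope-recovery checks use
100 taxa at 10⁵ reads/fraction and 50 replicates of n = 500 respectively. All
randomness flows from one root seed, split per stage with a CRC-based stable
hash, so identical configurations reproduce outputs byte for byte.

## Known limitations

- No per-taxon significance testing of density shifts (impossible in the
  single-pair design); the 0.10 cutoff is deliberately conservative.
- The BIOM support covers the JSON (v1) table layout only, not HDF5 BIOM.
- GC clamping handles noisy WADs crudely; heavily clamped datasets should be
  examined via the QC flags rather than trusted.
- Edge-of-gradient taxa (very high GC and AFE) are biased low by band
  truncation in both the simulator and, by construction, any real gradient.
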