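# dualqsip

Dual-isotope quantitative stable-isotope probing (qSIP) for microbial
communities: estimate per-taxon ¹³C **and** ¹⁵N atom fraction excess (AFE) from
CsCl density-gradient fractionation of paired labeled/unlabeled samples, call
enriched taxa, and analyse C/N co-enrichment — with a synthetic gradient
simulator that provides exact ground truth for every stage.

It is aimed at microbial ecologists running dual-label (e.g. ¹³C-glucose /
¹⁵N-ammonium, or isotopically labeled necromass) SIP experiments who have
per-fraction OTU count tables, fraction densities and DNA concentrations, and
want per-taxon enrichment estimates plus the standard downstream statistics.

## The model

A taxon's DNA bands in a CsCl gradient at a density set by its GC content
(Schildkraut: ρ = 1.66 + 0.098·GC) and its isotopic composition. qSIP tracks
the shift of the taxon's **weighted average density** (WAD) between unlabeled
and labeled samples, where each fraction's contribution is its relative read
abundance weighted by the fraction's DNA concentration:

    y_f  = p_f · D_f
    W    = Σ_f x_f y_f / Σ_f y_f
    GC   = (W_light − 1.66) / 0.098
    M_light    = 0.496·GC + 307.691
    M_heavymax = M_light + 9.974564 − 0.4987282·GC   (¹³C)
                 M_light + 3.517396 + 0.5024851·GC   (¹⁵N)
    M_lab = M_light · W_lab / W_light
    AFE   = (M_lab − M_light) / (M_heavymax − M_light) · (1 − a)

AFE is capped at 0.99 (the maximum permitted by 99 %-enriched media) and a
taxon is called enriched when its normalized AFE exceeds 0.10. Downstream, the
package partitions taxa into C-/N-/co-enriched sets, fits a standardized major
axis (model II) regression of AFE-N on AFE-C for co-enriched taxa with a
bootstrap slope CI, contrasts community AFE against substrate type and
incubation stage by OLS, and rarefies community tables by hypergeometric
subsampling.

## Worked example

Simulate the default study design (2 necromass types × {¹³C, ¹⁵N, unlabeled}
× 2 stages = 12 samples, 9 density fractions, 300 taxa with known truth),
estimate AFE for every labeled/unlabeled pair, and summarise enrichment:

```bash
dualqsip simulate --out data --seed 17
dualqsip afe --counts data/counts.tsv --fractions data/fractions.tsv \
             --manifest data/manifest.tsv --out afe.tsv
dualqsip enrich --afe afe.tsv --truth data/truth.tsv --out report
```

`afe.tsv` holds one row per taxon × labeled sample:

```
sample_id        otu_id   isotope  gc     wad_light  wad_labeled  afe_raw  afe_norm_percent  retained
low_earlier_13C  OTU0001  13C      0.565  1.71535    1.71894      0.0658    6.58             False
low_earlier_13C  OTU0002  13C      0.630  1.72175    1.73995      0.3332   33.32             True
low_earlier_13C  OTU0003  13C      0.546  1.71351    1.73125      0.3249   32.49             True
```

— OTU0002 shifted +0.018 g/mL between the unlabeled and ¹³C gradients, which
the chain converts to 33 % of its carbon atoms being ¹³C in excess of natural
abundance; OTU0001's 6.6 % sits below the 10 % retention threshold, so it is
not called enriched. `report/enrichment.json` then gives, per domain
(numbers printed by the run above):

```
bacteria: c_only 50, n_only 12, both 133, union 195, pct_c 94, pct_n 74
          SMA slope 1.114 (bootstrap CI 0.945–1.301), x-intercept 0.053
          13C melanin_low coefficient +0.116 (t = 12.1)
fungi:    c_only 20, n_only 3, both 75, union 98, pct_c 97, pct_n 80
          SMA slope 0.951 (CI 0.787–1.176)
```

i.e. most enriched taxa took up both elements, co-enrichment is strongly
positive with a slope near 1, and communities on the low-melanin substrate are
significantly more ¹³C-enriched — the structure the generator encodes and the
pipeline recovers. `dualqsip report --out out --seed 13` runs the whole chain
in one step; `dualqsip chem --out chem.tsv` recomputes the necromass C/N
bookkeeping from the packaged forage-fiber composition table.

See `docs/methods.md` for the model's assumptions, the simulator's noise
model, and numerical behaviour.

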