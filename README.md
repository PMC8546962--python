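# terroirseq

Vineyard-site signatures from grape-must microbiomes and fermentation
transcriptomes.

Inoculated wine fermentations carry a memory of where their grapes
grew: the bacterial (16S) and fungal (ITS) communities of the must, and
the S. cerevisiae transcriptome during fermentation, differ by vineyard
site, growing region and vintage — while the DNA profile of the must is
a poor predictor of which organisms are actually transcribing once
fermentation starts. `terroirseq` implements that analysis as a tested
pipeline for microbial ecologists and fermentation scientists, together
with a synthetic-study generator so every stage is verifiable without
any sequencing download.

The pipeline's core pieces, in the field's standard notation:

* **Compositional statistics** — relative abundance, centered log-ratio
  clr(x)ᵢ = ln(xᵢ/g(x)), Aitchison distance (Euclidean on CLR), Shannon
  H = −Σ pᵢ ln pᵢ and bias-corrected Chao1, and the 1%-abundance /
  90%-prevalence core microbiome.
* **Permutation tests** — ANOSIM R = (r̄_B − r̄_W)/(n(n−1)/4),
  single-factor PERMANOVA pseudo-F with R² = (SS_T − SS_W)/SS_T, and
  the Spearman Mantel test, all with p = (b+1)/(m+1) and exact
  enumeration for small n; NMDS (Kruskal stress-1); haversine
  geographic distances; BH false-discovery-rate adjustment.
* **DNA–RNA concordance** — per organism and timepoint, OLS of RNA
  relative abundance on must DNA relative abundance across
  fermentations, reporting adjusted R² (which may be negative).
* **Consensus random-forest signatures** — five-attribute time-series
  summaries (mean/min/max/total/sd per gene per fermentation),
  vita variable selection, seeded forests with OOB tuning, casewise
  (local) permutation importance, 70:30 and leave-one-vintage-out
  validation, and the strict intersection across S seeded models of
  genes with positive class-average local importance, with per-organism
  importance attribution.
* **Synthetic studies** — hierarchical Dirichlet-multinomial
  communities with single-genus dominance, inoculant-dominated
  transcriptomes with a calibrated DNA–RNA coupling (target R²),
  spatially autocorrelated climate, and a truth record for scoring
  recovery.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import terroirseq as tq

cfg = tq.ScenarioConfig.large_effect(seed=7)   # 15 sites, 8 regions, 2 vintages
study = tq.generate_study(cfg)

# Do fungal communities separate by site?
dm = tq.aitchison_distance(tq.clr_transform(study.fungal_counts))
sites = [s.split("-")[0] for s in study.fungal_counts.sample_ids]
res = tq.anosim(dm, sites, n_perm=999, seed=0)
print(f"ANOSIM R = {res.statistic:.3f}, p = {res.p_value:.3f}")

# Does must DNA predict fermentation RNA for the dominant yeast?
for r in tq.concordance_table(
    study.fungal_counts, study.transcript_counts, study.metadata,
    "Hanseniaspora uvarum", timepoints={2.0, 6.0, 16.0},
):
    print(f"{r.timepoint_hours:>5.0f} h: adj R2 = {r.r_squared:.2f}, p = {r.p_value:.3g}")
```

Output:

```
ANOSIM R = 0.980, p = 0.001
    2 h: adj R2 = 0.19, p = 0.000283
    6 h: adj R2 = 0.18, p = 0.000383
   16 h: adj R2 = 0.32, p = 1.7e-06
```

The near-maximal ANOSIM R says that, at this preset's effect sizes,
between-site community distances essentially always exceed within-site
distances; the modest adjusted R² values (the generator's coupling
target here is 0.25) quantify how weakly must DNA abundance predicts
the yeast's transcriptional activity — high abundance in the must does
not imply activity in the tank.

The same analyses are available from the shell:

```bash
terroirseq simulate --preset large-effect --seed 7 --out study/
terroirseq community-test study/fungal_ITS.tsv --metadata study/metadata.tsv \
    --marker ITS --test anosim --group site --permutations 999 --seed 0
terroirseq pipeline run --config run.yaml   # end-to-end with a manifest
```

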