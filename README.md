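# cardioage

Tools for asking *when* things change in an aging heart. Given bulk RNA-seq
counts from a cohort whose samples span the adult lifespan (the motivating
data are left-ventricle samples from female baboons aged 7.5–22.1 years,
human-equivalent ≈30–88), plus pathway gene sets and histology read-outs,
the package:

1. filters low-count transcripts and TMM-normalizes (`preprocess`);
2. groups transcripts into co-expression modules with a simplified
   WGCNA-style workflow — unsigned soft-threshold adjacency `|r|^β` (β = 12),
   topological overlap, average-linkage clustering, eigengene merging — and
   screens module eigengenes for age correlation (|r| ≥ 0.30, p ≤ 0.05)
   (`netmod`);
3. runs directional pathway enrichment: two-tailed Fisher's exact test,
   Benjamini–Hochberg control, and the activation z-score
   `z = Σᵢ xᵢ / √N` over member directions `xᵢ = ±1`, plus exact binomial
   tests for category skew (`enrich`);
4. fits each transcript's trajectory under both `y = B₀ + B₁x` and
   `y = B₀ + B₁x + B₂x²`, selects by the extra-sum-of-squares F test
   (α = 0.05), and extracts the **tipping point** — the vertex
   `−B₁/(2B₂)` at which a quadratic trajectory changes direction —
   aggregated per pathway as mean ± SD (`traj`);
5. fits a 4-parameter logistic to glycosaminoglycan staining fractions vs
   age and derives onset/end ages from the inflection tangent
   (`x₀ ∓ 2/k`) and the fast-accumulation window from where the tangent
   departs from the sigmoid (`onset`);
6. converts ages to human equivalents (×4) and assembles the ordered
   timeline of molecular events (`timeline`).

A synthetic-cohort generator (`synth`) plants known module structure,
trajectory vertices, pathway directions, and staining curves so the entire
pipeline is testable end-to-end without any external data.

## Worked example

Run the full chain on a synthetic cohort (35 samples, ages 7.5–22.1 years,
planted event order: metabolic downregulation → GAG metabolism →
hypertrophy signalling):

```sh
cardioage run-all --seed 1 --outdir demo/
```

prints the recovered timeline:

```
                       label          source  baboon_age_start  baboon_age_end  sd_years  human_age_start  human_age_end
            GAG accumulation staining_window         11.018529        21.38218       NaN               44           86.0
                  OXPHOS_TCA pathway_tipping         12.920739             NaN  0.574524               52            NaN
Cardiomyocyte width increase     morphometry         13.029971             NaN       NaN               52            NaN
                    NULL_SET pathway_tipping         13.561178             NaN  1.435628               54            NaN
       GAG fast accumulation staining_window         13.564879        18.83583       NaN               54           75.0
              GAG_METABOLISM pathway_tipping         14.088552             NaN  0.674108               56            NaN
         CARDIAC_HYPERTROPHY pathway_tipping         15.206976             NaN  0.483842               61            NaN
```

Reading it: the metabolic module's expression trajectory bends at
12.92 ± 0.57 years (planted truth 12.9), GAG-metabolism transcripts at
14.09 (planted 13.7) and hypertrophy transcripts at 15.21 (planted 14.6) —
the planted ordering is recovered. The staining sigmoid gives total GAG
accumulation over 11.0–21.4 years with a fast phase at 13.6–18.8, and the
cardiomyocyte-width quadratic bends at 13.0 years. `demo/` also holds the
per-stage tables (TMM factors, module labels, eigengene–age statistics,
enrichment results with Fisher/BH/z, per-transcript fits, staining fit
JSON). The same stages are available as individual subcommands
(`simulate`, `preprocess`, `modules`, `enrich`, `trajectories`, `onset`,
`timeline`) and as library functions.

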