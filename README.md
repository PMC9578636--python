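# testisquant

Quantitative phenotyping of *Drosophila melanogaster* testis confocal
stacks. The package implements, as a tested and reusable pipeline, the
measurement chain used in structure/function studies of spermatogenesis
and the germline stem-cell niche:

* **3D nuclei counting** — the z-stack is treated as one tensor, smoothed,
  thresholded, and split into nuclei by a marker-controlled watershed on
  the negated Euclidean distance transform (anisotropy-aware), plus
  per-slice density counts.
* **Niche-gated cell classification** — GSCs are Vasa⁺ *single* cells
  contacting the hub; CySCs are Zfh-1⁺ cells within 10 µm of the hub
  (surface-to-surface); marker-positive counts (Vasa, Zfh-1, Tj, Eya) per
  testis from intensity thresholds.
* **Pearson colocalization** — the voxel-wise coefficient
  r = Σ(aᵢ−ā)(bᵢ−b̄) / √(Σ(aᵢ−ā)² Σ(bᵢ−b̄)²) between two channels, e.g.
  endogenous Zpg versus a GFP-tagged variant, with joint-histogram
  scatter export.
* **Individualization-complex geometry** — the vertex angle between the
  actin-cone axis and the nuclear-bundle axis (180° = linear, wildtype-
  like; smaller = disorganized), measured in physical µm coordinates.
* **Spermatid-bundle counting** — single-linkage clustering of elongated-
  spermatid nuclei; a cluster of 64 syncytial nuclei is one bundle.
* **Fertility classification** — per-male daily offspring counts mapped
  to Fertile (>30), Subfertile (1–30), Infertile (0), summarized per
  genotype.
* **Group statistics** — mean ± SEM per genotype, one-way ANOVA with
  Tukey's multiple-comparison test (≥3 groups) or Welch's unpaired
  t-test (2 groups), with star notation \*p<0.05, \*\*p<0.01,
  \*\*\*p<0.001.

Because the original imaging data of such studies are rarely deposited,
the package ships a first-class **synthetic-data generator**
(`testisquant.synthetic_data`) that renders 3D multi-channel stacks with
known ground truth — blurred spherical nuclei with Poisson shot noise, a
hub blob, marker channels with controlled positivity, 64-nucleus
spermatid bundles, channel pairs with a target Pearson ρ, and
individualization complexes at a set angle — so every stage can be
validated by parameter recovery.

Intended users: fly labs quantifying testis phenotypes from confocal
stacks, and image-analysis developers who need a ground-truthed harness
for 3D counting and colocalization code.

## Worked example

Generate a small synthetic study (three pseudo-genotypes × 4 testes,
ground-truth GSC means 9 / 2 / 9) and run the full pipeline:

```bash
testisquant simulate demo --seed 2 --n-stacks 2
testisquant run demo/config.yaml
testisquant stats demo/results/summary.csv --value-col gsc_count
```

which prints:

```
null_like: mean 2.000 +/- 0.000 SEM (n = 2)
rescue_like: mean 9.000 +/- 0.000 SEM (n = 2)
wildtype_like: mean 9.000 +/- 0.000 SEM (n = 2)
null_like vs rescue_like: p = 0 ***
null_like vs wildtype_like: p = 0 ***
rescue_like vs wildtype_like: p = 1 ns
```

The niche classifier recovers the generated GSC counts exactly (9 GSCs
in the wildtype-like and rescue-like genotypes, 2 in the null-like one),
and the ANOVA+Tukey comparison flags the null-like genotype as different
from both others. Fertility rates from the same demo:

```bash
testisquant fertility demo/fertility.csv
# wildtype_like (n=12): 100.0% Fertile, 0.0% Subfertile, 0.0% Infertile
# null_like (n=12): 0.0% Fertile, 0.0% Subfertile, 100.0% Infertile
# rescue_like (n=12): 100.0% Fertile, 0.0% Subfertile, 0.0% Infertile
```

Single-stack operations are available as `segment`, `coloc`, `angles`,
`bundles`; e.g.

```bash
testisquant coloc demo/wildtype_like_00.tif --channel-a nuclear --channel-b vasa
# r = 0.7889 (n = 921600 voxels, nuclear vs vasa)
```

The same functionality is importable as a library; see
`testisquant.pipeline.run_pipeline` and the per-stage modules.

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
choices and known limitations.
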