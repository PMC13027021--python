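# deupanel

Analysis toolkit for **duplicate-measured expression panels across graded
deuterium concentrations**. NanoString-style panels report per-gene mRNA
copy counts in technical duplicate at four deuterium levels — 40, 80, 150
and 300 ppm, with 150 ppm (the natural isotopic abundance of body water) as
the physiological control. Starting from that counts table, the package
provides the full downstream analysis:

1. **QC filtering by propagated duplicate error.** Replicate disagreement at
   each concentration is summarised by the dimensionless statistic
   CV = |x₁ − x₂| / (x₁ + x₂). The relative error of each control-normalised
   expression ratio r_c = mean(c) / mean(control) is propagated from the two
   CVs entering it (quadrature by default), and the three per-ratio errors
   (40, 80, 300 ppm) are summed. Genes with total error > 0.55 or mean
   control count < 20 copies are excluded; an optional consensus-gene list
   restricts the panel further.
2. **Symbolic trajectory encoding.** Each ratio maps to one of five symbols
   (↓ < 0.70, ↙ 0.70–0.82, → 0.82–1.17, ↗ 1.17–1.37, ↑ > 1.37), turning a
   gene's (r40, r80, r300) profile into a triplet such as (→ ↓ ↗). The
   census counts realized patterns out of the 5³ = 125 possible and flags
   genes with singleton patterns.
3. **Three-way outlier consensus.** Sentinel genes are flagged by (a)
   Euclidean distance from the Global Center (the mean ratio profile, equal
   to the gene-count-weighted mean of pathway centroids), (b) DBSCAN noise
   in 3-D ratio space (ε = 0.13 by default, or chosen from the 5-distance
   curve; min_samples = 5), and (c) singleton symbolic patterns — combined
   in a Venn consensus.
4. **Tied-covariance Gaussian-mixture modules.** After outlier removal the
   profiles are clustered with a k-component Gaussian mixture sharing one
   covariance matrix Σ (p = (k−1) + 3k + 6 parameters, scored by
   BIC = −2L + p·ln n), scanned over k = 2–9 against full-covariance and
   k-means baselines, with Mahalanobis boundary-driver detection
   (d_M > 2.42), leave-one-out ARI stability and GMM-4 → GMM-6 transition
   tables.

A synthetic-data generator reproduces the study conditions (102 genes, six
planted expression modules, far-off sentinel outliers, planted QC failures)
with a ground-truth sidecar, so every stage is testable without the original
dataset.

## Worked example

```sh
deupanel simulate --seed 1 --out panel/
deupanel run-all --counts panel/counts.tsv --annotation panel/annotation.tsv \
    --out run/ --seed 1
```

or equivalently from Python:

```python
from deupanel import simulate, pipeline

panel = simulate.generate_panel(simulate.GeneratorConfig(seed=1))
paths = simulate.write_panel(panel, "panel")
manifest = pipeline.run_pipeline(pipeline.PipelineConfig(
    counts_path=str(paths["counts"]),
    annotation_path=str(paths["annotation"]),
    out_dir="run", seed=1))
print(manifest.stage_counts)
```

The run prints (and `run/report.txt` records):

```
Input genes: 102
Retained after QC: 94
  excluded_error: 6
  excluded_lowcount: 2
Observed trajectory patterns: 16 of 125 theoretical
Singleton patterns: 7
Density outliers (DBSCAN noise): 9
Genes clustered after outlier removal: 85
```

Reading: of 102 genes, the 6 planted high-dispersion genes and 2 planted
low-abundance genes fail QC (94 retained); the realized trajectory patterns
are sparse (16 of 125); DBSCAN flags the planted far-off profiles plus a few
noisy cluster-edge genes as density outliers, and the remaining 85 genes
enter the mixture scan (85 = 94 − 9). Every artifact — QC report, pattern
census, k-distance curve, DBSCAN labels, Venn regions, model scan, mixture
parameters, boundary drivers, leave-one-out stability, Sankey links — is a
plain TSV/JSON file in `run/`, and `run_manifest.json` records stage counts,
derived seeds and checksums. Identical seed and config reproduce
byte-identical outputs.

The estimators compose with scikit-learn: `TiedGMM`, `DeterministicDBSCAN`,
`DuplicateQCFilter` and `TrajectoryEncoder` follow the
fit/predict/transform, `get_params`/`set_params` conventions.

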