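# relapse-delta

Paired primary–relapse tumor transcriptome analysis for medulloblastoma
(MB) cohorts — and for any study design where each patient contributes a
matched diagnosis/recurrence pair of bulk RNA-seq profiles.

Written for computational biologists who want the full analysis chain of
a paired progression study as a tested, scriptable library: how much a
tumor's transcriptome moves at relapse, which genes drive the move,
how the cell-type composition shifts, and whether those shifts carry
prognostic weight.

## What it computes

**Pair-variance statistic.** Restrict log₂ RPKM expression to the top
*n* highly variable genes (default 500), project samples onto the top
*k* principal components (default 3), and measure each patient's
transcriptome change as

&nbsp;&nbsp;&nbsp;&nbsp;d(p) = ‖ s(primary_p) − s(relapse_p) ‖₂

in the joint PC space, where s(·) are PC scores. Group differences in
d are tested with Welch t-tests; covariate association (e.g. age) with
Pearson correlation.

**Pair-blocked moderated differential expression.** Within-pair
differences d_g = x_relapse − x_primary per gene collapse the paired
design to a one-sample problem; gene variances are shrunk by empirical
Bayes (moment-matched scaled-inverse-χ² prior on σ²_g) and the
moderated t uses the posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with d₀ + d_g degrees of
freedom, Benjamini–Hochberg adjusted. Over-representation of DEG lists
in GMT gene sets uses the upper-tail hypergeometric test.

**Composition deconvolution.** A labeled single-cell reference is
collapsed to six cell-subtype signatures (A1/A2 cell-cycle, B1/B2
undifferentiated progenitors, C1/C2 differentiated neuronal-like);
each bulk CPM profile is decomposed by weighted non-negative least
squares, min ‖W(S·f − b)‖₂ s.t. f ≥ 0, renormalized to relative
fractions, with a permutation goodness-of-fit p. Primary→relapse shifts
are tested per cell type with paired t-tests, stratified by molecular
group, and cross-checked by a rank-based single-sample enrichment score
over the same marker sets.

**Survival.** Kaplan–Meier, log-rank, Cox proportional hazards (Efron
ties, via lifelines), a cutoff scan that tries every expression value in
the 10th–90th percentile window as a high/low split and Bonferroni-
corrects the minimal log-rank p by the number of cutoffs tested, and
metagene construction: prognostic, direction-concordant relapse-up genes
pool into an *unfavorable* metagene (mean z-scored expression),
relapse-down genes into a *favorable* one.

**Fingerprint.** SNV variant-allele fractions are thresholded into
genotype codes; a primary/relapse pair is verified when the genotype
concordance over jointly covered sites reaches 0.8.

**Synthetic cohort generator.** All of the above is exercisable without
patient data: `synthetic_cohort` simulates 43 patient pairs
(24 SHH / 5 Group 3 / 14 Group 4 by default) as negative-binomial counts
around Dirichlet-mixed cell-type signature profiles, with programmed
relapse composition shifts (Group 3/4: cell-cycle A1 ×1.5 up, C1 down;
SHH: progenitor B1 up, C1 down), designated DE genes, CNV block
effects, metagene-linked censored survival, and shared per-patient SNP
fingerprints — every effect recorded as ground truth.

## Worked example

```python
import numpy as np
from relapse_delta.synthetic_cohort import SimulationConfig, simulate_cohort, simulate_sc_reference
from relapse_delta import normalization, pair_variance, paired_dge, composition
from relapse_delta.matrix_io import pair_index

cfg = SimulationConfig(seed=7)
counts, gene_info, ann, truth = simulate_cohort(cfg)
log = normalization.log2_rpkm(counts, gene_info)

res = pair_variance.analyze_cohort(log, ann)
print("variance pct of top 3 PCs:", np.round(res.variance_pct, 1))
print("median pair distance:", round(res.distances.median(), 2))
grouping = ann.table.drop_duplicates("patient_id").set_index("patient_id")["group"]
print(pair_variance.compare_groups(res.distances, grouping)[["group1", "group2", "t", "p"]].round(3))

sub = ann.subset_groups(["G3", "G4"])
fit, table = paired_dge.run_paired_dge(log, pair_index(sub))
degs = paired_dge.select_degs(table)
print("prior df d0 =", round(fit.d0, 1),
      "; DEGs up/down in relapse:", len(degs["up"]), "/", len(degs["down"]))

bulk = normalization.cpm(counts)
sc, labels = simulate_sc_reference(cfg, truth.signature_profiles)
sig = composition.build_signature(sc, labels, 50)
fr = composition.deconvolve_nnls(bulk, sig, n_perm=0)
row = composition.compare_fractions(fr, ann).query("stratum == 'G4' and cell_type == 'A1'").iloc[0]
print(f"G4 A1 fraction: primary {row['mean_primary']:.3f} -> relapse {row['mean_relapse']:.3f} "
      f"(paired t p={row['p']:.4f})")
```

Output:

```
variance pct of top 3 PCs: [11.   8.2  3.4]
median pair distance: 9.06
  group1 group2      t      p
0     G3     G4 -0.580  0.570
1     G3    SHH  2.001  0.067
2     G4    SHH  2.334  0.027
prior df d0 = 74.6 ; DEGs up/down in relapse: 60 / 38
G4 A1 fraction: primary 0.132 -> relapse 0.246 (paired t p=0.0001, n=14)
```

Reading it: the top three PCs carry ~23% of expression variance; Group
3/4 pairs sit further apart in PC space than SHH pairs (Welch p = 0.027
for G4 vs SHH); the moderated test calls 98 differentially expressed
genes between primary and relapse in the merged Group 3/4 cohort with a
prior worth d₀ ≈ 75 extra degrees of freedom per gene; and deconvolution
recovers the programmed ~1.9-fold increase of the A1 cell-cycle subtype
in this cohort realization of Group 4 relapses.

The same workflow runs end to end from the shell:

```bash
relapse-delta simulate --out-dir data --seed 7
relapse-delta normalize --counts data/counts.tsv --gene-info data/gene_info.tsv --out data/log2rpkm.tsv
relapse-delta variance --expr data/log2rpkm.tsv --ann data/annotation.tsv --subset group=SHH --out-dir out/
relapse-delta fingerprint --vaf data/vaf.tsv --ann data/annotation.tsv --out out/fp.tsv
```

or as one pipeline with a manifest of content-hashed artifacts:
`relapse-delta run --config cfg.yaml`.

## Layout

| module | contents |
| --- | --- |
| `matrix_io` | TSV/GMT readers and writers, expression/annotation containers, pairing, cohort summary |
| `normalization` | log₂ RPKM, CPM, low-expression filter |
| `pair_variance` | HVG selection, PCA scores, pair distances, group tests, covariate correlation |
| `paired_dge` | paired differences, empirical-Bayes moderated t, BH, DEG selection, hypergeometric ORA |
| `composition` | signature building, weighted NNLS deconvolution, paired fraction tests, enrichment scores |
| `survival` | KM, log-rank, cutoff scan, metagenes, Cox, categorical association tests |
| `fingerprint` | genotype calls from VAF, pair concordance verdicts |
| `synthetic_cohort` | the paired cohort / single-cell reference / VAF generator with ground truth |
| `pipeline`, `cli` | end-to-end orchestration, YAML config, hashed manifest, `relapse-delta` CLI |

See `docs/methods.md` for the statistical details, generator design and
known limitations.
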