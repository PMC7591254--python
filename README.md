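# microrepop

Most microglia die without CSF1R signalling, yet a small subpopulation
survives pharmacological CSF1R inhibition and rapidly rebuilds the
microglial pool once the inhibitor is withdrawn. Single-cell RNA-seq of
mouse microglia across three conditions — untreated (Ctrl), the end of a
two-week inhibitor course (D0), and two days of repopulation (D2) — shows
that the survivors include a MAC2/Galectin-3 (*Lgals3*)-high subpopulation
with an immature, progenitor-like transcriptome: up-regulated yolk-sac and
early-embryonic microglial genes (*Lyz2*, YS/E1 signatures), down-regulated
homeostatic markers (*Tmem119*, *P2ry12*, *Cx3cr1*, *Csf1r*, *Mafb*).

`microrepop` implements that analysis as a reusable, tested pipeline, with
a synthetic-data generator (planted ground truth) standing in for the raw
data, plus the immunofluorescence colocalization quantification. It is
aimed at computational biologists who want to run, audit, or adapt the
chain:

1. **Simulation** — three-condition cohorts with five myeloid and four
   contaminant populations, NB counts, lognormal library sizes, a planted
   Lgals3-high program.
2. **QC** — 500 ≤ UMI ≤ 20,000, ≥ 200 genes, ≤ 10% mitochondrial counts,
   genes in ≥ 10 cells.
3. **Clustering** — log-normalisation, covariate regression, top-3000
   variable genes, PCs 1–10, SNN-Leiden, marker-panel contaminant removal.
4. **Gating** — MAC2+ cells called where log-normalised *Lgals3* exceeds
   mean + 1 SD (all cells pooled, strict inequality).
5. **Differential expression** — a two-part hurdle model per gene:
   a binomial likelihood-ratio test on detection plus a Gaussian LRT on the
   positive log-expression values, summed and referred to chi-square with
   the informative degrees of freedom; fold change as
   ln(mean(eˣ − 1) + 1) differences with 0.25 / 0.5 thresholds.
6. **Signatures** — overlap of DEG lists with the seven developmental stage
   sets (YS, E1, E2, P1, P2, A1, A2) and Venn comparisons.
7. **Abundance** — per-cluster NB GLM on cells-per-cluster counts with
   log(sample total) offset and a quasi-likelihood deviance F test per
   condition contrast.
8. **Imaging** — adaptive-threshold segmentation per channel, colocalization
   when masks overlap by strictly more than 10% of the smaller mask,
   phenotype counts and per-cell intensities anchored on IBA1.

## Worked example

```python
from microrepop.simulate import default_params, generate_counts
from microrepop.qc import apply_qc
from microrepop.preprocess import log_normalize
from microrepop.gating import gate_positive, condition_frequencies

params = default_params(n_cells_per_sample=400, seed=20201)
matrix = generate_counts(params)           # 2000 genes x 3200 cells
matrix, report = apply_qc(matrix)
norm = log_normalize(matrix)
gate = gate_positive(norm.gene_vector("Lgals3"), k_sd=1.0)
print(condition_frequencies(gate, matrix.cell_meta["condition"].to_numpy()))
```

```
condition  n_positive  n_total   pct
     Ctrl          77     1062   7.3
       D0         126     1065  11.8
       D2         105      706  14.9
```

The per-condition MAC2+ percentages rise from Ctrl through D0 to D2,
mirroring the planted program fractions (3.0% / 9.8% / 11.2%); the gated
values sit a few points higher because the mean+1SD rule also captures the
upper tail of Lgals3 expression in non-program cells (against the planted
labels this run scores sensitivity 0.93, specificity 0.95). For reference,
the published count pairs 300/10103, 1004/10209 and 633/5642 give exactly
3.0%, 9.8% and 11.2%.

The full analysis, from simulation through imaging, runs as numbered
drivers:

```sh
python analysis/01_simulate.py   # synthetic cohort -> results/data/tenx
python analysis/02_qc.py
python analysis/03_cluster.py    # 13 clusters -> strip -> 2833 myeloid cells, ARI 0.91
python analysis/04_gate.py
python analysis/05_differential_expression.py
python analysis/06_signatures.py # up-DEGs hit YS/E1; down-DEGs hit A1/A2
python analysis/07_abundance.py  # proliferative cluster: p < 2e-4 for D0 vs Ctrl
python analysis/08_imaging.py
```

or end-to-end from one config via the CLI:

```sh
microrepop run-all --seed 7 --outdir run
microrepop imaging --tiff field.tif --channels IBA1,MAC2 --out counts.csv
```

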