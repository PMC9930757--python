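# woundage

Screening mRNA indicators for forensic wound age estimation.

## The problem

Estimating how long before death an injury was inflicted ("wound age") is a
recurring problem in forensic pathology. qPCR measurement of mRNA levels in
contused skeletal muscle is a standard approach, but a good marker must do
two things at once: change reproducibly with time since injury, and vary as
little as possible *between individuals* sampled at the same time point. A
marker that is heterogeneous across animals is useless for casework no
matter how strongly it responds to injury.

`woundage` implements a screening framework that ranks candidate mRNAs by
between-individual homogeneity and validates the ranking with a
discriminant wound-age model. Candidates are stratified by two biological
features hypothesised to govern expression stability:

* **ARE structure** — AU-rich elements in the 3'UTR accelerate mRNA decay;
  candidates are called ARE+ or ARE- from a curated database flag plus a
  local motif score with a strict > 3 threshold;
* **GO category** — cellular component (CC), biological process (BP), or
  molecular function (MF); genes annotated to more than one category are
  excluded.

The cross of the two gives six subgroups (ARE-CC ... ARE+MF).

## The method

For a design of a control group plus 12 contusion time points (4-48 h,
4-h steps, n = 6 animals each):

1. **Quantification.** Relative expression per animal and gene from the
   efficiency-corrected comparative-Ct model
   `expression = (1 + Eff.)^-ΔΔCt`, with Eff. estimated per gene from a
   five-fold dilution standard curve (`Eff. = 10^(-1/slope) - 1`), ΔCt
   taken against the mean of the RPL13/RPL32 reference genes, and ΔΔCt
   centred on the control-group mean.
2. **Homogeneity.** Per (gene, time point): MD (mean absolute deviation),
   STD (sample SD), d% = MD/mean, CV = STD/mean. Per gene: the **CV score
   (CVs)** — at each time point genes are ranked by ascending CV and the
   quartiles earn 4/3/2/1 points, summed over the 12 contusion time points
   (higher = more homogeneous) — and **CV'CV**, the coefficient of
   variation of the gene's CV series across time points (lower = a more
   stable heterogeneity profile).
3. **Wound-age model.** A multi-class Fisher (pooled-covariance linear)
   discriminant over each gene grouping (ARE+/-, CC/BP/MF, and the six
   crosses), with Wilks' λ = det(W)/det(T) and Bartlett's χ² significance,
   evaluated by leave-one-out cross-validation.

Because the original per-animal measurements are not publicly deposited,
the package ships a first-class synthetic-data generator that emulates the
study design — planted ARE motifs in simulated 3'UTRs, gene-specific
amplification efficiencies, smooth time-course profiles, and lognormal
between-animal noise whose magnitude is set per subgroup — so every stage
is testable end to end.

## Worked example

```bash
woundage run-all --seed 1 --out-dir run1
```

writes the full set of tables (gene panel, UTR FASTA, Ct table, dilution
series, expression matrix, dispersion metrics, per-gene scores, subgroup
summary, discriminant summary, confusion matrices, manifest). The same in
Python:

```python
from woundage import run_synthetic_study, dispersion_table, score_table
from woundage import aggregate_subgroups, discriminant_summary

panel, expr = run_synthetic_study(seed=1)
disp = dispersion_table(expr)
scores = score_table(expr)
print(aggregate_subgroups(disp, scores, panel.records).round(3))
```

```
          n_genes     md    std  d_pct     cv  cv_of_cv     cvs
subgroup
ARE+BP          4  0.571  0.743  0.223  0.290     0.306  19.500
ARE+CC          4  0.329  0.434  0.186  0.247     0.294  23.500
ARE+MF          4  0.271  0.357  0.258  0.343     0.292  15.750
ARE-BP          5  0.203  0.264  0.154  0.202     0.323  29.000
ARE-CC          6  0.142  0.187  0.074  0.097     0.317  45.167
ARE-MF          5  0.173  0.230  0.111  0.144     0.337  37.800
```

The ARE-CC subgroup has the lowest mean CV (0.097, i.e. ~10%
between-animal variation) and the highest CV score (45.2 of a possible
48), exactly the pattern the generator's graded subgroup dispersions plant
(ARE-CC most homogeneous). The discriminant models agree:

```python
table, confusions = discriminant_summary(expr, panel.records)
print(table.round(4))
```

```
        n_genes  wilks_lambda  p_value  loocv_accuracy_pct
subset
ARE+         12        0.0001      0.0             47.4359
ARE-         16        0.0000      0.0             92.3077
CC           10        0.0000      0.0             89.7436
BP            9        0.0000      0.0             70.5128
MF            9        0.0000      0.0             79.4872
ARE-CC        6        0.0000      0.0             91.0256
...
```

The homogeneous ARE- genes estimate wound age far better under
leave-one-out cross-validation (92.3%) than the noisy ARE+ genes (47.4%),
and ARE-CC is the best of the six crossed subsets (91.0%); Wilks' λ near 0
with p < 0.05 indicates strongly separated time-point classes.

## Command-line interface

```
woundage simulate     --seed N --out-dir DIR [--config cfg.yaml]
woundage arescan      --fasta utrs.fa --threshold 3 --out calls.tsv
woundage quantify     --ct ct.csv --curves dilutions.csv --qc qc.csv --out expr.csv
woundage homogeneity  --expr expr.csv --panel genes.csv --out-dir DIR
woundage discriminate --expr expr.csv --panel genes.csv --out table.csv
woundage run-all      --seed N --out-dir DIR [--config cfg.yaml]
```

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
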