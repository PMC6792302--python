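# subtypebench

An evaluation-and-comparison platform for multi-omics cancer-subtyping
methods.

Integrating several omics layers (mRNA expression, miRNA expression,
DNA methylation, copy-number variation) to discover cancer subtypes is
a crowded methodological field, and different integrators routinely
disagree — both with each other and across candidate numbers of
subtypes k.  Because gold standards are rare, choosing a method
requires systematic comparison rather than a single benchmark number.
`subtypebench` is built for researchers facing that choice: it runs
every selected subtyping method for every k from 2 to a user-chosen
k-max, evaluates each run with clustering metrics and clinical survival
analysis, pools all runs into a robust consensus co-clustering, and —
when expert-defined subtypes are available — flags the best method with
a weighted score.  Your own method's results can join the comparison
alongside the built-ins.

## What it computes

For p methods and k ∈ 2..k_max the platform performs p×(k_max−1) runs
and reports per run:

- **Cox p-value** — likelihood-ratio test of a proportional-hazards
  model with k−1 subtype indicators (p < 0.05 suggests clinically
  meaningful subtypes), plus Kaplan–Meier curves per subtype;
- **silhouette coefficient** `SC = mean (b−a)/max(a,b)` on the method's
  integrated patient-distance matrix;
- **NMI** `2I(X;Y)/(H(X)+H(Y))` and **ARI** (chance-corrected pair
  agreement) against expert labels when available, and the mean NMI/ARI
  against all other methods at the same k otherwise;
- a **consensus matrix** `CM = Σ_t M(t)` summing the binary
  co-membership matrices of all runs, clustered hierarchically into a
  consensus subtyping;
- a **performance score**
  `0.5·z(−log10 Cox p) + (0.5/3)·(z_NMI + z_ARI + z_SC)` that weighs the
  clinical and clustering halves equally and flags the best method.

It also selects the reduced dimension of a low-rank embedding
automatically from its explained-variance curve via the *adjusted
turning score* (relative EV differences damped by `|Δx|^2.2`, penalized
toward the curve's interior) — see `docs/methods.md` for all formulas
and conventions.

A synthetic-cohort generator (`subtypebench simulate` /
`subtypebench.generate_cohort`) produces multi-omics cohorts with
planted subtypes, controllable separation, missing values and
subtype-dependent survival, so the whole pipeline is testable without
any data download.

## Worked example

Simulate a 60-patient, 3-subtype cohort with two layers, then run the
full comparison with the two built-in baseline integrators (`concat`:
z-score + stack + best-of-300-restarts k-means; `simfuse`: fused
Gaussian patient similarity + spectral clustering):

```sh
subtypebench simulate --n-samples 60 --n-subtypes 3 \
    --layer mrna:100:5 --layer methylation:80:5 \
    --hazard 0.02 --hazard 0.08 --hazard 0.2 \
    --seed 1 --out demo
subtypebench run --layer mrna=demo/mrna.tsv \
    --layer methylation=demo/methylation.tsv \
    --survival demo/survival.tsv --truth demo/true_labels.tsv \
    --k-max 5 --seed 1 --out demo/report
```

which prints:

```
 method  k        cox_p       sc      nmi      ari  runtime_seconds
 concat  2 2.037061e-01 0.576732 0.733680 0.562963         0.065287
 concat  3 8.927128e-08 0.782688 1.000000 1.000000         0.048070
 concat  4 4.504295e-08 0.512541 0.907358 0.870044         0.043528
 concat  5 5.359260e-07 0.184303 0.827273 0.718112         0.054146
simfuse  2 2.037061e-01 0.692903 0.733680 0.562963         0.012704
simfuse  3 8.927128e-08 0.940053 1.000000 1.000000         0.015291
simfuse  4 4.504295e-08 0.586463 0.907358 0.870044         0.019641
simfuse  5 9.075248e-07 0.581579 0.871195 0.839997         0.021414
best method at k=3: simfuse
```

Both baselines recover the three planted subtypes exactly at k = 3
(NMI = ARI = 1) with a highly significant survival split
(p ≈ 9·10⁻⁸), while k = 2 merges two subtypes (ARI ≈ 0.56, p ≈ 0.2) —
the k-dependence the platform exists to expose.  At the true k the
weighted score prefers `simfuse` for its tighter clusters
(SC 0.94 vs 0.78).  `demo/report/` contains the machine-readable
`report.json`, the metric/agreement/score tables as TSV, the consensus
vote matrix and labels, and KM-curve data (plus PNG heatmaps with
`--plots`).

The library mirrors the CLI one-to-one (`generate_cohort`,
`run_scenario`, `select_dimension`, `performance_score`, …); see the
docstrings and `docs/methods.md`.

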