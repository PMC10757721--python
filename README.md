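# efferotype

Transcriptomic subtyping of diffuse glioma around an efferocytosis
(apoptotic-cell clearance) gene program, as a tested, fully synthetic-data-
validated Python pipeline:

* **Subtype discovery** — consensus non-negative matrix factorization
  (generalized-KL multiplicative updates, multi-restart connectivity
  consensus), with cophenetic/dispersion stability metrics and automatic
  rank selection at the first cophenetic decrease.
* **Subtype transfer** — a nearest-shrunken-centroid classifier
  (soft-thresholded standardized centroid deviations, cross-validated
  shrinkage) with Mann–Whitney ROC AUC evaluation.
* **Immune regulation networks** — per-gene tertile discretization, a 66%
  mid-or-high prevalence filter, and edges scored by the concordance index
  CI = (n_HH + n_LL)/(n_LH + n_HL) over a protein-interaction catalog
  seeded by ligand/receptor genes (CI > 1, isolated nodes pruned), with hub
  genes from the intersection of Maximal Clique Centrality
  (MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!) and degree rankings.
* **Gene-set scoring** — a rank-weighted single-sample enrichment score and
  preranked GSEA with permutation p-values.
* **Survival** — Kaplan–Meier/log-rank, Cox proportional hazards (Efron
  ties), an exact points-based nomogram over the multivariate fit, IPCW
  time-dependent AUC and calibration curves, plus point-biserial drug
  correlation and TIDE-score responder thresholding.

Real cohorts at the scale the original study used are not redistributable,
so the package ships a synthetic cohort generator
(`efferotype.synthetic`) that plants known subtypes (hazard ratio 5.583 vs
the planted C2, age hazard 1.070/year), a 137-gene program, and coupled
ligand–receptor pairs, making every stage testable against ground truth.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (the cohort itself is written under `scratch/`, small result tables
under `results/analysis/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_discover_subtypes.py
python analysis/03_transfer_classifier.py
python analysis/04_immune_network.py
python analysis/05_score_genesets.py
python analysis/06_survival_nomogram.py
```

Output of the discovery and survival steps (seed 7):

```
selected rank: 2
  rank 2: cophenetic 1.000  dispersion 1.000
  rank 3: cophenetic 0.983  dispersion 0.667
  rank 4: cophenetic 0.944  dispersion 0.552
ARI against planted subtypes: 1.000
...
log-rank C1 vs C2: chi2 26.6, p 2.51e-07
  multivariate subtype[C2]: HR 0.171 (0.106-0.275)
  multivariate age: HR 1.067 (1.052-1.083)
  nomogram time-dependent AUC at 365 d: 0.831
```

Reading: the cophenetic coefficient is maximal at two clusters and drops
beyond, so two subtypes are selected; the recovered labels match the
planted truth exactly (ARI 1.0). In the survival model the C2 indicator's
hazard ratio of 0.171 is the planted C1-vs-C2 ratio seen from the other
side (1/0.171 ≈ 5.9 vs 5.583 planted), and the age effect per year (1.067)
matches the planted 1.070. The same workflow is scriptable end-to-end with
a manifest via `efferotype run --config cfg.yaml`, or stage by stage with
the `efferotype` subcommands (`simulate`, `preprocess`, `subtype`,
`classify`, `network`, `score`, `survival`) on your own TSV inputs.

As a library:

```python
from efferotype import CohortConfig, generate_cohort, subtype_cohort, log2_tpm

cohort = generate_cohort(CohortConfig(seed=7))
labels, by_rank, rank = subtype_cohort(log2_tpm(cohort.expression),
                                       cohort.signature, ranks=[2, 3, 4],
                                       n_restarts=10, base_seed=7)
print(rank, labels.value_counts().to_dict())   # 2 {'C1': 100, 'C2': 100}
```

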