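# lowrankdti

Drug–target interaction (DTI) prediction by graph-regularized nuclear-norm
matrix completion with bilinear factorization.

Experimentally confirming which drugs bind which protein targets is slow
and expensive; computational ranking of candidate pairs narrows the search
space.  `lowrankdti` treats the known interactions as a partially observed
binary matrix Y (drugs × targets) and recovers a low-rank score matrix Z
by solving

```
min_{rank(Z) ≤ r}  ½‖P(Y) − P(Z)‖²_F + λ‖Z‖_*
                   + α₁·Tr(Zᵀ L_d Z) + α₂·Tr(Z L_t Zᵀ)
```

where P is the observation mask, ‖Z‖_* the nuclear norm, and L_d, L_t
graph Laplacians built from five drug–drug and five target–target
similarity matrices (one provided — chemical structure / sequence
similarity — plus cosine, correlation, Hamming and Jaccard similarities of
the interaction profiles).  The nuclear norm is handled through its
bilinear form ‖Z‖_* = min_{ABᵀ=Z} ½(‖A‖² + ‖B‖²), optimized by a
rank-restricted soft SVD (alternating ridge regression with
re-orthogonalization); the graph terms enter through Sylvester-equation
smoothing steps.  Cross-validated evaluation supports the three standard
blinding protocols — random pairs (CVS1), whole drugs (CVS2), whole
targets (CVS3) — with AUC and AUPR.

The package is aimed at computational chemogenomics: method developers who
need a clean, tested reference for nuclear-norm DTI completion, and
practitioners ranking candidate interactions on the public gold-standard
benchmarks (enzymes, ion channels, GPCRs, nuclear receptors) or their own
adjacency tables.

## Worked example

```python
import lowrankdti as lr

inst = lr.generate(lr.SyntheticSpec(seed=42))      # 60 drugs x 50 targets
params = lr.default_params()                        # benchmark-tuned defaults
drug_set = lr.combine_similarities(inst.drug_sim, inst.data.values,
                                   "drug", p_nn=params.p_nn)
target_set = lr.combine_similarities(inst.target_sim, inst.data.values,
                                     "target", p_nn=params.p_nn)
result = lr.fit(inst.data, drug_set, target_set, params)
print(len(result.trace.objective), result.converged)

report = lr.run_experiment(inst.data, inst.drug_sim, inst.target_sim,
                           params, scheme="CVS1", n_reps=1, n_folds=10,
                           base_seed=0)
print(report.summary())
```

Output:

```
3 True
{'auc': '0.8414 (0.0755)', 'aupr': '0.5299 (0.1314)'}
```

The fit converged in 3 outer iterations (each: two Sylvester solves + one
nuclear-norm proximal step) with a monotonically decreasing objective.
Under tenfold pair-blinded cross-validation the model ranks held-out cells
with mean AUC 0.84 and mean AUPR 0.53 over folds (sample standard
deviations in parentheses).  AUPR is the stricter number here because true
interactions are rare (5% of cells); the same experiment with the graph
terms switched off (`alpha1=alpha2=0`) gives 0.8364 / 0.5032, so the
similarity graphs contribute a consistent improvement on identical folds.

The `examples/` directory holds one short script per capability:
simulation + completion, similarity/Laplacian construction, fitting,
cross-validated evaluation, and the paired regularization comparison.

## Command line

```bash
lowrankdti simulate --m 60 --n 50 --rank 4 --density 0.05 --seed 42 --out inst/
lowrankdti similarities --interactions inst/interactions.txt --out sims/
lowrankdti fit --interactions inst/interactions.txt \
    --drug-sim inst/drug_sim.txt --target-sim inst/target_sim.txt \
    --lambda 0.1 --rank 4 --scores-out scores.txt
lowrankdti evaluate --interactions inst/interactions.txt \
    --drug-sim inst/drug_sim.txt --target-sim inst/target_sim.txt \
    --scheme CVS1 --folds 10 --reps 5 --report-out report.tsv
```

All flags mirror a YAML/JSON `--config` file; explicit flags win.  Tables
are tab-delimited labeled matrices in the dialect of the public
gold-standard DTI files (use `--orientation targets_in_rows` for files
stored with targets in rows, e.g. the downloaded benchmark tables).

## Layout

```
src/lowrankdti/
  data_io.py      labeled-matrix tables, InteractionData/ScoreMatrix
  similarity.py   profile similarities, p-NN sparsification, Laplacians
  solvers.py      SVT oracle, rank-restricted soft SVD, masked completion,
                  Sylvester solves, convergence statistic
  model.py        the graph-regularized model (fit/predict/objective)
  evaluation.py   CVS1/CVS2/CVS3 folds, AUC/AUPR, experiment runner
  synthetic.py    low-rank instance generator with correlated similarities
  cli.py          thin click CLI over the above
docs/methods.md   model, algorithms, design choices, limitations
examples/         one narrative script per capability
```
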