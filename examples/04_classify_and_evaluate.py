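"""Full pipeline on the synthetic benchmark with cross-validated evaluation.

Runs PCA -> Laplacian smoothing -> self-supervised pretraining -> multi-label
DNN under 5-fold CV and prints macro/micro AUPR and Fmax, overall and per
term-frequency group.
"""

from phenolink import SyntheticSpec, benchmark_config, generate_dataset, run_benchmark

dataset = generate_dataset(SyntheticSpec(n=150, seed=17))
result = run_benchmark(dataset, benchmark_config(seed=0))

for scope, metrics in result.report.scopes.items():
    row = ", ".join(
        f"{k}={v:.3f}" if v is not None else f"{k}=n/a" for k, v in metrics.items()
    )
    print(f"{scope:>8}: {row}")
# M- metrics average per phenotype term (sensitive to rare terms); m- metrics
# flatten the gene x term matrix (dominated by frequent terms). Scores well
# above the ~0.2 label prevalence indicate the embeddings carry real signal.
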