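"""Simulate a two-group scRNA-seq dataset and cluster it with scSPaC.

Draws a small gamma-Poisson count matrix with strong group differential
expression, runs the full pipeline (filter → HVG → log-scale → self-paced
NMF → K-means) and scores the result against the known groups.
"""

import scspac

params = scspac.SimParams(n_genes=2000, de_prob=0.5, de_facscale=1.5, seed=0)
counts = scspac.simulate_counts(params)
print(f"simulated {counts.n_genes} genes x {counts.n_cells} cells, "
      f"groups: {sorted(set(counts.labels))}")

processed = scspac.preprocess_pipeline(counts, scspac.PreprocessConfig(n_hvg=1000))
print(f"model input X: {processed.X.shape[0]} HVGs x {processed.X.shape[1]} cells")

result = scspac.fit(processed, scspac.SPaCConfig(norm="frobenius", r=2, seed=0))
clusters = scspac.kmeans_embed(result.factors, K=2, seed=0)
report = scspac.evaluate(clusters.assignments, processed.labels)

pct = report.as_percent()
print(f"ARI={pct['ari']:.1f}  purity={pct['purity']:.1f}  NMI={pct['nmi']:.1f}  (x100)")
print("1.0/100 on all three means the two simulated cell groups were "
      "recovered exactly; chance level is ARI/NMI ~ 0, purity ~ 50.")
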