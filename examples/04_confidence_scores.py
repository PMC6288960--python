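"""Quantify how stable a continent prediction is: RC and NC scores.

Reference-confidence (RC) bootstraps the reference panel: how often does a
resampled panel reproduce the full-panel KNN prediction? NGS-confidence
(NC) re-predicts from disjoint subsets of the query's own reads: how often
do independent read subsets agree with the modal call?
"""

from kmergeo import (
    SimulationConfig,
    build_sample_data,
    knn_predict,
    ngs_confidence,
    pairwise_matrix,
    reference_confidence,
    simulate_readsets,
)

cfg = SimulationConfig(genome_length=50_000, n_individuals=6, bases_per_sample=50_000, seed=3)
readsets, metas = simulate_readsets(cfg)
labels = {m.sample_id: m.continent for m in metas}
ids = sorted(readsets)
samples = {sid: build_sample_data(readsets[sid], k=8, m=2, measure="d2star") for sid in ids}
dm = pairwise_matrix([samples[s] for s in ids], "d2star")

query = "EU_03"
pred = knn_predict(dm, labels, query, K=3)
print(f"query {query}: predicted {pred.predicted} "
      f"(votes {pred.votes}, nearest {pred.neighbor_ids[0]})")

rc = reference_confidence(dm, labels, query, K_values=(1, 3), B=500, seed=7)
print(f"RC(K=1) = {rc[1]:.2f}, RC(K=3) = {rc[3]:.2f} over 500 bootstrap panels")

refs = [samples[s] for s in ids if s != query]
nc, modal, preds = ngs_confidence(
    readsets[query], refs, labels, k=8, m=2, n_subsets=5, seed=8
)
print(f"NC = {nc:.2f}: {preds.count(modal)}/{len(preds)} disjoint read subsets "
      f"agree on {modal}")
# RC = NC = 1.00 means the call survives both resampling of the reference
# panel and halving/splitting of the query's own sequence data
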