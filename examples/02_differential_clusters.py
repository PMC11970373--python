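"""Classify union regions into gain / loss / common clusters.

Builds the 10-kb / 50-bin signal matrix around each region centre for
both conditions, k-means-clusters the concatenated rows, and labels each
cluster by the pseudocounted fold change between condition means.
"""

from collections import Counter

from k9diff import (
    ClusterConfig,
    MatrixConfig,
    PeakCallConfig,
    SimulationConfig,
    UnionConfig,
    call_broad_peaks,
    classify_clusters,
    extract_signal_matrix,
    kmeans_cluster,
    quantile_normalize,
    simulate_dataset,
    subtract_input,
    union_regions,
)
from k9diff.differential import cluster_condition_means

config = SimulationConfig(seed=7)
repeats, truth, tracks = simulate_dataset(config)

ips = tracks.by_role("IP")
inputs = tracks.by_role("input")
reduced = {s.condition: subtract_input(t_ip, t_in)
           for s, t_ip, t_in in zip(ips, quantile_normalize([s.track for s in ips]),
                                    quantile_normalize([s.track for s in inputs]))}

cfg = PeakCallConfig(30, 15, min_peak_length=400)
union = union_regions([call_broad_peaks(t, cfg) for t in reduced.values()],
                      UnionConfig(), genome=config.genome_model())

matrix = extract_signal_matrix(reduced, union, MatrixConfig(window=10_000, n_bins=50))
assignment = kmeans_cluster(matrix, ClusterConfig(k=8, seed=7))
labels = classify_clusters(cluster_condition_means(matrix, assignment, ("A", "B")))
region_labels = [labels[int(c)] for c in assignment]

print(f"{len(union)} regions in {len(set(assignment))} k-means clusters")
print("regions per label:", dict(Counter(region_labels)))

# compare with the generator's truth at the label level
truth_counts = Counter(truth.labels)
print("planted per label: ", dict(truth_counts))
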