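"""Degree-limited prediction network with known-edge trimming.

Candidate pairs passing the FDR cutoff are linked to their most similar
known partners, capped at three edges per node; components whose edges are
all previously known are trimmed away so novel predictions stand out.
"""

import numpy as np

import harmonet as hn

rng = np.random.default_rng(4)
candidates = [f"cand{i}" for i in range(15)]
references = [f"ref{i}" for i in range(10)]
preds = [
    hn.ScoredPrediction(
        (c, references[int(rng.integers(10))]),
        float(rng.random()), float(rng.random()),
    )
    for c in candidates for _ in range(4)
]
# treat the two heaviest candidate pairs as already catalogued
survivors = sorted(
    (p for p in preds if p.estimated_fdr <= 0.67), key=lambda p: -p.score
)
known = {survivors[0].subject, survivors[1].subject}

net = hn.build_network(preds, fdr_cutoff=0.67, max_edges_per_node=3,
                       known_edges=known)
print(f"{len(net.edges)} edges survive the FDR 0.67 cutoff and the "
      f"3-edges-per-node cap (max degree {net.max_degree()})")
print(f"{sum(e.known for e in net.edges)} edges are already-known associations")

trimmed = hn.trim_known_clusters(net)
print(f"after trimming all-known components: {len(trimmed.edges)} edges remain "
      "(every remaining component contains at least one novel prediction)")
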