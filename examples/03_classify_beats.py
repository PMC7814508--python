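"""Classify held-out beats with the logical network, including the anomaly path.

Each motif is a class-tagged node; a test beat takes the label of its
nearest node, unless even the nearest node is at distance >= r — then the
beat is flagged ANOMALY for future learning.  A clinician-confirmed
anomaly motif can be pushed back into the network with add_node.
"""

import numpy as np

from ecgmotif import (CohortSpec, Motif, MotifParams, add_node, build_network,
                      classify, classify_batch, discover_motifs, make_cohort,
                      prepare_cohort_beats, stratified_prefix_split)

beats = prepare_cohort_beats(make_cohort(CohortSpec(seed=42)))["p00"]
train, test = stratified_prefix_split(beats, t=0.2)
params = MotifParams(r=1.0, k=1)
net = build_network(
    discover_motifs([b for b in train if b.label == "N"], params),
    discover_motifs([b for b in train if b.label == "V"], params),
    r=params.r, patient_id="p00")
print(f"network: {len(net.nodes)} nodes ({net.labels})")

predictions = classify_batch(test, net)
correct = sum(p.predicted == b.label for p, b in zip(predictions, test))
anomalies = sum(p.predicted == "ANOMALY" for p in predictions)
print(f"{correct}/{len(test)} beats correct, {anomalies} flagged as anomalies")

# a beat unlike anything in training is flagged, then learned
odd = np.roll(test[0].vector, 60) * -1.0
print("distorted beat ->", classify(odd, net).predicted)
learned = add_node(net, Motif(center=odd, label="V", rank=99, member_count=1,
                              member_indices=frozenset({0}), radius=params.r))
print("after add_node ->", classify(odd, learned).predicted)
print("The anomaly path is what lets the model defer unfamiliar morphology")
print("to a clinician instead of forcing an N/V decision.")
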