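"""Score candidate gene pairs with a trained model.

After training, any pair of KG genes can be scored: each gene's multi-hop
receptive field is sampled, encoded conditioned on its partner, and the
sigmoid inner product of the two encodings is the SL probability (threshold
0.5 for a hard label).  Here a few pairs from the untouched test split are
scored against their true planted labels.
"""

import numpy as np

from slkgnn import SyntheticSpec, generate_kg, plant_sl_labels, predict_pairs, train_model
from slkgnn.synthetic import benchmark_config

spec = SyntheticSpec(seed=1)
kg, assignment = generate_kg(spec)
data = plant_sl_labels(assignment, spec, seed=1)
cfg = benchmark_config(seed=1)
params, _ = train_model(data, kg, cfg)

test = data.subset("test")
candidates = [p for p in test if p.label == 1][:4] + [p for p in test if p.label == 0][:4]
ga = np.array([p.gene_a for p in candidates])
gb = np.array([p.gene_b for p in candidates])
probs = predict_pairs(params, kg, ga, gb, cfg, eval_seed=99)

ids = [e.raw_id for e in kg.entities]
print("gene_a,gene_b,true_label,shares_factor,probability,label@0.5")
for p, prob in zip(candidates, probs):
    shares = bool(assignment[p.gene_a] & assignment[p.gene_b])
    print(f"{ids[p.gene_a]},{ids[p.gene_b]},{p.label},{shares},{prob:.4f},{int(prob >= 0.5)}")
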