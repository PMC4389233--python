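"""Split regulated enhancers into p53-bound (BER) and p53-free (FER) and
profile transcription drop-off downstream of the bidirectional midpoint."""

import numpy as np

from ernaflow import SimulationConfig, simulate_dataset
from ernaflow.classify import (
    BER,
    FER,
    ClassifiedEnhancer,
    UnidirectionalRegionError,
    bidirectional_midpoint,
    dropoff_profile,
)
from ernaflow.pipeline import run_pipeline

dataset = simulate_dataset(SimulationConfig(seed=1))
result = run_pipeline(dataset)

n_ber = sum(1 for c in result.classified if c.p53_class == BER)
n_fer = len(result.classified) - n_ber
print(f"regulated enhancers: {len(result.classified)}  ({n_ber} BER / {n_fer} FER)")

# midpoint of bidirectional transcription from the pooled treated replicates
treated = dataset.read_index(
    [s for s, c in dataset.conditions.items() if c == "treated"]
)
with_midpoints = []
for ce in result.classified:
    try:
        mid = bidirectional_midpoint(ce.region, treated)
    except UnidirectionalRegionError:
        continue
    with_midpoints.append(
        ClassifiedEnhancer(region=ce.region, p53_class=ce.p53_class, midpoint=mid)
    )

profiles, q75 = dropoff_profile(with_midpoints, treated, bin_bp=100, max_bp=2000)
for cls in (BER, FER):
    dists = [q75[e.region.region_id] for e in with_midpoints if e.p53_class == cls]
    print(f"median q75 drop-off distance {cls}: {np.median(dists):.0f} bp  "
          f"(n={len(dists)})")

# Bound enhancers are planted with a tighter transcription drop-off than
# free ones, so the BER median q75 distance comes out shorter than the FER
# median, mirroring the biological expectation that p53-bound enhancers
# produce more compact bidirectional transcripts.
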