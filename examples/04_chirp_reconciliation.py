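"""Reconcile lncRNA ChIRP peaks from the odd/even probe pools and measure
enrichment in chromatin states and in induced enhancers."""

from ernaflow import SimulationConfig, simulate_dataset
from ernaflow.chirp import (
    CoverageTrack,
    bound_enhancer_enrichment,
    filter_chirp_peaks,
    reconcile_pools,
    remove_contaminants,
    state_enrichment,
)
from ernaflow.diff import INDUCED
from ernaflow.pipeline import run_pipeline

dataset = simulate_dataset(SimulationConfig(seed=1))

odd = filter_chirp_peaks(dataset.chirp_odd_peaks)
even = filter_chirp_peaks(dataset.chirp_even_peaks)
print(f"pool peaks after q>=5 / enrichment>=4 filter: odd {len(odd)}, even {len(even)}")

merged = reconcile_pools(
    odd,
    even,
    CoverageTrack(dataset.chirp_odd_cov),
    CoverageTrack(dataset.chirp_even_cov),
)
clean = remove_contaminants(merged, dataset.contaminant_blacklist)
print(f"reconciled binding sites: {len(merged)} "
      f"({len(merged) - len(clean)} plasmid contaminants removed)")

print("\nstate enrichment (first cell line):")
for e in state_enrichment(clean, dataset.tracks[0]):
    print(f"  {e.category:8s} observed {e.observed:3.0f}  expected {e.expected:6.2f}"
          f"  fold {e.fold:6.1f}  p {e.p_value:.3g}")

result = run_pipeline(dataset)
universe = {c.region_id for c in result.candidates}
bound = {
    c.region_id
    for c in result.candidates
    if any(c.interval.overlaps(m.interval) for m in clean)
}
induced = set(result.verdicts[result.verdicts == INDUCED].index)
enr = bound_enhancer_enrichment(bound, induced, universe)
print(f"\ninduced enhancers among lncRNA-bound ones: {enr.observed:.0f} observed vs "
      f"{enr.expected:.1f} expected (fold {enr.fold:.1f}, hypergeometric "
      f"P = {enr.p_value:.2e})")

# Only sites replicating across both probe pools (coverage correlation >=
# 0.2, >= 25 reads each) survive; the designated strong-enhancer state shows
# the top enrichment fold, and binding concentrates on induced enhancers far
# beyond chance.
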