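"""Nucleotide-resolution termination profiling of one valve design.

Maps reads back to the design reference, filters truncation artifacts, builds
the read-depth profile, and reports: the termination efficiency Te (the
fractional depth drop across the valve), the called termination position(s)
from the Δ-profile, and the U-tract content at the dominant position.
"""

import numpy as np

import valveseq as vs

designs = vs.synthetic_design_library(1, 1, 1, seed=3)
d = designs[0]
model = vs.default_truth_model(d, true_te=0.65)
(true_pos,) = model.termination_weights

cfg = vs.SimulationConfig(substitution_rate=0.15, reads_per_design=800, seed=4)
reads, truth = vs.simulate_pool([d], {d.id: model}, cfg)

mapped = [m for m in (vs.map_read(r.id, r.sequence, d) for r in reads) if m is not None]
kept, removed = vs.filter_reads(mapped, d)
profile = vs.build_depth_profile(kept, len(d.reference_sequence), d.id)
m = vs.measure_valve(profile, d)

print(f"design {d.id}: {len(kept)} reads kept, {len(removed)} removed by the filter")
print(f"true Te = 0.65; empirical terminated fraction = {truth['is_terminated'].mean():.4f}")
print(f"measured Te (raw) = {m.te_raw:.4f}  "
      f"[depth {m.depth_at_xs} at valve start -> {m.depth_at_xe} at valve end]")
print(f"dominant termination position = {m.dominant_position} (truth: {true_pos})")
print(f"called points (position: weight): "
      + "; ".join(f"{p}:{w:.2f}" for p, w in m.termination_positions))
print(f"U residues in the 8-nt U-tract at the dominant position: {m.u_count}")
print(f"terminated:read-through isoform ratio = {vs.isoform_stoichiometry(m.te_raw):.2f}:1")
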