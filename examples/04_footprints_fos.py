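"""TF footprint detection and time-of-day occupancy dynamics.

Simulates cut tracks for six genotype x time conditions over one toy genome in
which footprints are deeply occupied only in wild-type at ZT04.  Detects
footprints at ZT04 and ZT16 in wild-type, splits them into time-specific sets,
extracts smoothed average Tn5 profiles, and compares inverse footprint
occupancy scores across all conditions with Kruskal-Wallis + Dunn letters.
"""

import numpy as np

from rhythmatac.footprints import (
    compare_fos_groups,
    extract_profiles,
    footprint_fdr,
    fos,
    rolling_average,
    timepoint_specific,
)
from rhythmatac.synthetic import SimGenomeConfig, simulate_cut_tracks, simulate_genome

cfg = SimGenomeConfig(seed=4)
seqs, _, peaks, truth = simulate_genome(cfg)
lengths = {s: len(q) for s, q in seqs.items()}
conditions = {
    ("WT", 4.0): 0.9, ("WT", 16.0): 0.3,
    ("ClkKO", 4.0): 0.3, ("ClkKO", 16.0): 0.3,
    ("CycLike", 4.0): 0.3, ("CycLike", 16.0): 0.3,
}
truth.depth_factors = conditions
tracks = {
    cond: simulate_cut_tracks(truth, cond, lengths, seed=40 + i)
    for i, cond in enumerate(conditions)
}

fp04, fdr04 = footprint_fdr(tracks[("WT", 4.0)], peaks, n_shuffles=5, seed=44)
fp16, fdr16 = footprint_fdr(tracks[("WT", 16.0)], peaks, n_shuffles=5, seed=45)
spec04, spec16, shared = timepoint_specific(fp04, fp16)
print(f"WT ZT04 footprints: {len(fp04)} (empirical FDR {fdr04:.3f})")
print(f"WT ZT16 footprints: {len(fp16)} (empirical FDR {fdr16:.3f})")
print(f"ZT04-specific {len(spec04)} | ZT16-specific {len(spec16)} | shared {len(shared)}")

prof = extract_profiles(tracks[("WT", 4.0)], spec04)
avg = rolling_average(prof.mean(axis=0).to_numpy(), w=3)
center, flank = avg[90:111].mean(), np.r_[avg[:40], avg[-40:]].mean()
print(f"\nZT04-specific average profile: center {center:.2f} vs flank {flank:.2f} cuts/bp")

records = []
for cond, track in tracks.items():
    records.extend(fos(track, fp, group=cond) for fp in spec04)
res = compare_fos_groups(records)
print(f"\nKruskal-Wallis on inverse FOS: H = {res['kw_stat']:.1f}, p = {res['kw_p']:.2e}")
print("group letters (shared letter = not significantly different):")
for grp in sorted(res["letters"]):
    print(f"  {grp:14s} {res['letters'][grp]}  median inv FOS {res['group_medians'][grp]:.2f}")
# Only WT_ZT04 carries deep footprints, so it takes a letter of its own with
# the highest median inverse FOS, mirroring clock-dependent TF occupancy.
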