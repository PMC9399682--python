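"""Rank selected features by the |ln|w|| importance scale.

Reproduces the published worked example: the packaged reference table of
40 cortical features carries one signed aggregated weight per feature;
its importance is the absolute natural log of the weight magnitude, and
rank 1 is the largest importance.  Because every surviving |w| is below
1, rank 1 corresponds to the smallest-magnitude weight.
"""

from adcascade import importance, load_reference_features, rank_features, round_half_up

ref = load_reference_features()
report = rank_features(list(zip(ref["feature_id"], ref["w"])))

print("top five features by |ln|w||:")
for e in report.entries[:5]:
    print(f"  rank {e.rank}: {e.feature_id:32s} w={e.w: .3e}  |ln|w||={e.importance:.3f}")

w = 2.906e-5  # left anterior occipital sulcus, fractal dimension
print(f"\nworked example: w = {w:.3e}  ->  |ln|w|| = {round_half_up(importance(w))}")
print("(matches the published importance of the top-ranked feature, 10.446)")
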