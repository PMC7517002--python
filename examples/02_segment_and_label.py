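"""Generate a video-induction-shaped dataset, segment it, and label by
valence-arousal quadrant.

Each of the 40 trials is 63 s at 128 Hz with a 3 s leading baseline; after
dropping the baseline, ten 6 s windows per trial give 400 analysis samples.
Rating-pair labels (1-9 valence/arousal) resolve to the four quadrants.
"""

from collections import Counter

from emosig import deap_like, generate_dataset, resolve_label, segment_recording

recordings = generate_dataset(deap_like(), seed=7)
print(f"trials: {len(recordings)}, duration {recordings[0].duration_s:.0f} s, "
      f"channels {list(recordings[0].channels)}")

segments = [
    seg
    for rec in recordings
    for seg in segment_recording(rec, window_s=6.0, drop_baseline_s=3.0)
]
print(f"segments after 3 s baseline removal: {len(segments)}")

counts = Counter(resolve_label(seg.label) for seg in segments)
print("per-quadrant segment counts:", dict(sorted(counts.items())))

v, a = recordings[0].label
print(f"\nexample: trial {recordings[0].recording_id} rated "
      f"valence={v:.2f}, arousal={a:.2f} -> {resolve_label(recordings[0].label)}")
print("Ratings above 5 count as High, at or below 5 as Low, so each trial"
      "\nfalls in exactly one of HVHA / HVLA / LVLA / LVHA.")
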