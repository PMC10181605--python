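"""The sliding hands-off time (sHOT) over the 26-point decision grid.

Extracts one period of interest and prints, per decision time, how much
artefact-free ECG the 10 s analysis window contains. Before the
regular analysis starts (t <= 0) sHOT reflects insufflation pauses;
afterwards it grows by exactly 1 s per step until it saturates at the
analysis duration.
"""

from cprshock import analysis_windows, make_dataset

ds = make_dataset(n_patients=4, seed=3)
poi = next(iter(ds.pois.values()))
print(f"period {poi.poi_id}: rhythm {poi.label.value}, "
      f"{poi.n_samples} samples on (-30 s, +10 s]")
print(f"compression episodes (relative clock): {poi.timeline.cc_episodes}\n")

print(" t(s)  sHOT(s)  [D = 10 s window (t-10, t]]")
for w in analysis_windows(poi, duration=10):
    bar = "#" * int(round(w.shot))
    print(f"{w.decision_time:+4d}   {w.shot:5.2f}   {bar}")
print("\nsHOT is bounded by the duration D; windows fully inside a "
      "compression episode score 0.")
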