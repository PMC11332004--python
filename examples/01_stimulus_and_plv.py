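"""Generate the accelerating stimulus and measure one participant's PLV.

Builds the 60 s syllable-train envelope (4.3 -> 4.7 Hz in 0.1 Hz
plateaus), simulates one tightly coupled and one self-paced producer,
and runs the synchrony measurement chain on each.
"""

import speechsync as ss

spec = ss.StimulusSpec()  # 5 plateaus x 12 s = 60 s
stim = ss.generate_stimulus_envelope(spec)
print(f"stimulus: {stim.duration_s:.0f} s, "
      f"{len(ss.detect_burst_times(stim))} syllables")

stim_banded = ss.resample_and_band(stim)  # 100 Hz, 3.5-5.5 Hz, zero phase

for label, pspec in [
    ("coupled (kappa=16)", ss.SyntheticParticipantSpec(coupling_kappa=16.0, seed=1)),
    ("self-paced 3.5 Hz", ss.SyntheticParticipantSpec(mode="self_paced", seed=1)),
]:
    prod = ss.simulate_production(stim, pspec, stim_spec=spec)
    pair = ss.phase_pair(stim_banded, ss.resample_and_band(prod))
    res = ss.compute_plv(pair)  # 5 s windows, 2 s overlap
    print(f"{label}: PLV = {res.plv_mean:.3f} over {res.n_windows} windows")

# A PLV near 1 means the produced syllable bursts held a stable phase
# relation to the heard stream; the self-paced producer drifts through
# all phases and stays near the chance floor.
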