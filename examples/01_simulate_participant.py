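"""Generate a virtual participant and inspect what the generator encodes.

The generator emulates a ~3-year implanted-EEG recording: daily seizure
counts from a cyclically modulated Poisson intensity, an hourly IED rate
phase-locked to the same cycles, a mid-recording drug change, recording
gaps, and a diary that captures only a fraction of detected events.
"""
import numpy as np

from szproject import SimulationConfig, simulate_intensity, simulate_participant

config = SimulationConfig(seed=11, drug_effect=0.5, drug_transient=(45, 0.5))
vp = simulate_participant(config)

lam = simulate_intensity(config)
print(f"days simulated:          {config.n_days}")
print(f"mean intensity:          {lam.values.mean():.2f} seizures/day")
print(f"seizures detected:       {len(vp.seizure_events)}")
print(f"diary entries:           {len(vp.diary_events)} "
      f"({100 * len(vp.diary_events) / len(vp.seizure_events):.1f}% of detected)")
print(f"IED samples (hourly):    {len(vp.ied_rates)}, "
      f"{int(vp.ied_rates.missing.sum())} in recording gaps")
print(f"regimens: {[(str(a.date()), str(b.date()), lab) for a, b, lab in vp.regimen_intervals]}")

# The intensity halves at the drug change (day 300): the generator's
# ground truth that the analysis pipeline must later recover from counts.
print(f"intensity day 299 vs 400: {lam.values[299]:.2f} -> {lam.values[400]:.2f} seizures/day")
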