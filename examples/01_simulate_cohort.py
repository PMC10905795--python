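"""Generate a small synthetic cohort and inspect its structure.

Each patient gets five recording sessions (T1..T5, one day) whose latent
coupling matrices differ according to the diagnosis group's variability
profile; the realized per-session coupling is kept as ground truth.
"""

import numpy as np

from eegnetvar import simulate_cohort

cohort = simulate_cohort(n_per_group=2, duration_s=40.0, seed=7)

print(f"{len(cohort)} patients, {sum(len(p.sessions) for p in cohort)} recordings")
for patient in cohort:
    rec = patient.sessions[0]
    drift = np.mean([
        np.abs(t - patient.ground_truth[0]).mean()
        for t in patient.ground_truth[1:]
    ])
    print(f"  {patient.patient_id:9s} group={patient.group:7s} CRS-R={patient.crsr:2d} "
          f"fs={rec.fs:.0f} Hz  shape={rec.data.shape}  "
          f"mean |coupling drift| across sessions = {drift:.3f}")

print("\nThe drift column tracks session-to-session movement of the latent "
      "coupling matrix, which is driven by hub rotation and so is largest "
      "for EMCS.  The VS/UWS profile's variability instead lives in the "
      "background (noise) state, which rescales the measured connectivity "
      "wholesale without moving the coupling matrix itself.")
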