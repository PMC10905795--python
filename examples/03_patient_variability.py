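"""Large-timescale variability for one patient's five daily sessions.

NMI compares module partitions of neighboring session patterns (1 = same
modular organization), GEV is the variance share explained by the average
pattern, and CV is the relative spread of each network statistic over the
five sessions.
"""

import numpy as np

from eegnetvar import default_base_coupling, default_profiles
from eegnetvar.pipeline import analyze_patient
from eegnetvar.synthetic import simulate_patient

base = default_base_coupling()
for profile in default_profiles():
    patient = simulate_patient(profile, base, patient_id=profile.label,
                               crsr=sum(profile.crsr_range) // 2,
                               duration_s=150.0, fs=500.0, seed=11)
    var, metrics, _ = analyze_patient(patient.sessions)
    print(f"{profile.label:7s} NMI(T_k,T_k+1)={np.round(var.nmi_series, 2)} "
          f"mean={var.nmi_mean:.2f}  GEV={var.gev:.2f}")
    print(f"        CV: path length={var.cv_cpl:.3f}  clustering={var.cv_cc:.3f} "
          f"mean betweenness={var.cv_bc_mean:.3f}")

print("\nHigher CV of path length / clustering for the VS/UWS profile "
      "reflects its unstable background state; session-to-session hub "
      "rotation in EMCS concentrates variability at centro-parietal "
      "electrodes instead.")
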