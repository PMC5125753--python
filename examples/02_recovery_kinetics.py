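"""Photo-conversion decay analysis, end to end.

Simulates a pulse-labelled RNA decay curve (63% anchored, a fast
nonspecific component and a slow RNA component), then runs the full
correction-and-fitting pipeline: bi-exponential fit with the
nonspecific half-time fixed at its nurse-cell calibration (3.2 min),
removal of the nonspecific component, single-exponential refit, and
compensation of the slow MCP-MS2 dissociation (0.0017 / min).
"""

import numpy as np

import mrnatrack as mt
from mrnatrack import kinetics as kin

params = mt.RecoverySimParams(
    mode="photoconversion", F_IM=0.63, C_NS=0.20, C_RNA=0.17,
    tau_NS=3.2, tau_RNA=26.0, koff=kin.KOFF_MS2_CLOOP, noise_sd=0.005,
    t_points=np.linspace(0.0, 55.0, 56), seed=7)
series = mt.simulate_recovery(params)

biexp = kin.fit_biexponential(series, "photoconversion", tau_NS_fixed=3.2)
print("bi-exponential fit (nonspecific half-time fixed at 3.2 min):")
print(f"  immobile fraction F_IM:  {biexp.F_IM:.3f}   (truth 0.63; biased low "
      "because coat-protein dissociation is not yet compensated)")
print(f"  nonspecific C_NS:        {biexp.C_NS:.3f}   (truth 0.20)")
print(f"  RNA mobile C_RNA:        {biexp.C_RNA:.3f}   (truth 0.17)")
print(f"  RNA half-time tau_RNA:   {biexp.tau_RNA:.1f} min (truth 26)")

rna_only = kin.remove_nonspecific(series, biexp)
rna_only = kin.compensate_ms2_dissociation(rna_only)
single = kin.fit_single_exponential(rna_only, "photoconversion")
print("\nRNA-specific signal after nonspecific removal and MS2 compensation:")
print(f"  immobile fraction:       {single.F_IM:.3f} of RNA-specific signal "
      "(truth 0.63/0.80 = 0.79)")
print(f"  fluorescence half-time:  {single.tau:.1f} min")
print()
loss = (1 - np.exp(-kin.KOFF_MS2_CLOOP * 55)) * 100
print(f"Without compensation, coat-protein dissociation alone would remove "
      f"{loss:.1f}% of signal over 55 min ({loss:.0f}% to the nearest percent).")
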