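"""EEG band powers: from a raw derivation to night-level SWA and SWE.

Simulates a short night of stage-dependent synthetic EEG, scores each 30-s
epoch with the ten-window Hann FFT scheme, and prints per-stage slow-wave
activity.  Deep sleep (N3) is delta-dominant by construction, so its SWA
(ln µV²) should sit several log units above wake.
"""

import numpy as np

from psgequiv import (SimConfig, derive, score_derivation, simulate_eeg,
                      simulate_hypnogram, summarize_spectra)

cfg = SimConfig(trt_minutes=10.0, master_seed=7)
hyp = simulate_hypnogram(cfg, subject=0, night=1)
rec = simulate_eeg(cfg, hyp, subject=0, night=1)
sig = derive(rec, "F3", "M2")

per_epoch = score_derivation(sig, hyp)
for ep in per_epoch:
    stage = hyp.stages[ep.epoch_index]
    print(f"epoch {ep.epoch_index:2d}  stage {stage:>2s}  "
          f"SWA = {ep.values['swa']:6.2f} ln µV²  "
          f"({ep.n_windows_used} windows)")

summary = summarize_spectra(per_epoch, hyp)
print(f"\nNREM mean SWA  = {summary.swa_mean_nrem:.2f} ln µV² "
      f"over {summary.n_epochs_nrem} N2+N3 epochs")
print(f"slow-wave energy = {summary.swe:.2f} ln µV² "
      f"({summary.swe_convention} convention)")
print("\nSWA is the 0.5-4 Hz band power; SWE accumulates it over NREM.")
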