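"""Score a staged hypnogram into the standard sleep variables.

Builds the 10-epoch worked example by hand and prints every derived
variable.  With one arousal during 3 minutes of sleep the arousal index is
1/3 x 60 = 20 events per hour of sleep; terminal wake counts toward WASO so
SL + TST + WASO equals the 5-minute recording exactly.
"""

from psgequiv import Hypnogram, compute_sleep_variables

hyp = Hypnogram(
    stages=["W", "W", "N1", "N2", "N2", "N3", "R", "W", "N2", "W"],
    arousals=[(120.0, 5.0)],
)
sv = compute_sleep_variables(hyp)

print(f"TRT  = {hyp.trt_minutes:.1f} min over {hyp.n_epochs} epochs")
for name, value in sv.as_dict().items():
    print(f"{name:>12s} = {value:.2f}")
print("\nTST counts every epoch of N1/N2/N3/R; percentages are of TST;")
print("NREM latencies run from lights-off, stage-R latency from sleep onset.")
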