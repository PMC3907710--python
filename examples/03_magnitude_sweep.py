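"""Reward-magnitude sweep: thresholds for cue learning and cancelation.

Trains fresh networks on a single cue-reward association across a grid of
reward magnitudes and prints how the cue response and the reward-burst
cancelation depend on magnitude.  Uses a reduced grid (5 magnitudes x 3
networks); pass more points/networks for smoother curves.
"""

from vtanet.protocol import run_magnitude_sweep, summarize_sweep

df = run_magnitude_sweep([0.1, 0.3, 0.5, 0.8, 1.0], n_networks=3, seed=0)
summary = summarize_sweep(df)

print("magnitude  cue resp (BLA, trial 15)  reward burst trial 1 -> 15 (VTA)")
for mag in sorted(df["magnitude"].unique()):
    row1 = summary[(summary.magnitude == mag) & (summary.trial == 1)].iloc[0]
    row15 = summary[(summary.magnitude == mag) & (summary.trial == 15)].iloc[0]
    print(f"  {mag:4.1f}    {row15.cs_bla_mean:10.2f}             "
          f"{row1.us_vta_mean:5.2f} -> {row15.us_vta_mean:5.2f}")

# Small rewards evoke proportional bursts but never engage learning: the
# cue response appears only above a magnitude threshold, and the burst
# cancelation (trial-15 value well below trial-1) only for large rewards.
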