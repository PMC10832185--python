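"""Secretome rates, Z trajectories, clustering and the transcript lead.

Secreted-protein concentrations are converted to ng/mL/day rates, Z-scored
longitudinally, clustered (Manhattan/Ward), and compared with their source
transcript profiles by a lagged-correlation scan.  Noise-free, the injected
2-day delay is recovered exactly; with measurement noise single estimates
can wobble by a day but stay inside the expected 1-3 day window.
"""

import pandas as pd

import gliostate as gs

_, truth = gs.simulate_counts(gs.default_design(seed=1))
sec = gs.simulate_secretome(
    truth,
    [("Galectin3", "dam"), ("Spp1", "dam"), ("Tnfa", "acute_injury")],
    lag_days=2.0, noise_sd=0.1, seed=3,
)
rates = gs.to_rates(sec)
z = gs.longitudinal_zscores(rates)
print("rate Z-scores (rows = analytes, columns = culture days):")
print(z.values.round(2).to_string())

tree = gs.cluster_secretome(z)
print("cluster leaf order:", tree.leaf_order)
# The two chronic-block analytes pair up; the acute-block analyte, whose
# secretion pulse follows the day-1 transcript burst, sits apart.

for name, block in [("Galectin3", "dam"), ("Tnfa", "acute_injury")]:
    protein = pd.Series(
        z.values.loc[name].to_numpy(), index=[float(c) for c in z.values.columns]
    )
    lag, per_lag = gs.estimate_lag(truth.block_transcript_z(block), protein)
    print(f"{name}: estimated lag {lag:.0f} d  (r by lag: "
          + ", ".join(f"{int(k)}d={v:+.2f}" for k, v in per_lag.items()) + ")")
# Transcript changes lead secretion, with estimates inside the 1-3 day
# window expected for transcription -> translation -> release.  The chronic
# trajectory is smooth, so adjacent lags correlate almost equally and noise
# can shift a single estimate by one day; across seeds the mode is 2 days.
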