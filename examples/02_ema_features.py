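"""The non-neural baselines: identity (raw) and EMA/EMV features.

Embeds one 60-minute oxygen-saturation window two ways and prints the
4-dimensional EMA/EMV summary: three exponential moving averages at
smoothing factors 0.1, 1 and 5, plus one exponential moving variance at
factor 5.  alpha=1 collapses to the last observed value; alpha=0.1 is a
slow average of roughly the last 10-20 minutes; the variance term
captures recent instability.
"""

import numpy as np

import vitalembed as ve

rng = np.random.default_rng(0)

# a stable window, then one with a downward drift in the final minutes
stable = 97.5 + rng.normal(0, 0.8, size=60)
drifting = stable.copy()
drifting[45:] -= np.linspace(0, 4, 15)

# span mode reads alpha=5 as a span (smoothing factor 2/(alpha+1)=1/3);
# the default literal mode applies the printed recursion verbatim, under
# which alpha>1 produces sign-alternating weights of huge magnitude —
# well defined and fine for scale-invariant tree models, but unreadable.
params = ve.EmaParams(literal_mode=False)

for name, window in (("stable", stable), ("drifting", drifting)):
    raw = ve.embed_raw(window)          # identity: all 60 minutes
    feats = ve.embed_ema(window, params)  # (EMA .1, EMA 1, EMA 5, EMV 5)
    print(f"{name:>9}: last minute {raw[-1]:6.2f} | "
          f"EMA(0.1)={feats[0]:6.2f}  EMA(1)={feats[1]:6.2f}  "
          f"EMA(5)={feats[2]:6.2f}  EMV(5)={feats[3]:6.2f}")

print("\nThe slow average (EMA 0.1) barely moves under the drift while the")
print("last value drops ~4 units; the variance term flags the instability.")
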