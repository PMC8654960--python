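"""Train per-signal embedding models and evaluate transfer between hospitals.

Runs the end-to-end driver under the pinned two-hospital study
conditions (three signals, 16-dimensional embeddings, label-scarce
downstream windows, densely scored test split) at a reduced cohort size:
self-supervised next-5-minute LSTMs are trained per signal at each
hospital, windows are embedded (each model applying its own training
normalization), a gradient-boosted-tree forecaster is fitted on the
target hospital, and every plan is scored by average precision with a
99% bootstrap interval.  'next' uses target-trained models; the
'next-transferred' plan applies the *other* hospital's models without
any target-side model training — the cross-hospital transfer setting.

~3 minutes on one CPU.  A single cohort and direction is one draw from a
noisy comparison; scripts/acceptance.py runs the multi-seed,
both-directions version whose medians are stable.
"""

import vitalembed as ve
from vitalembed.benchmark import benchmark_config

config = benchmark_config(seed=23,
                          plans=("raw", "ema", "rand", "next",
                                 "next-transferred"))

result = ve.run_experiment(config)
cols = ["plan", "ap", "roc_auc", "ci_low", "ci_high", "pct_improvement"]
print(result.table[cols].round(4).to_string(index=False))
print(f"\ntest windows: {result.table['n_test'].iloc[0]}, "
      f"hypoxemia base rate {result.table['base_rate'].iloc[0]:.1%}")
print("AP is the area under the precision-recall curve; pct_improvement")
print("is each plan's AP gain over the raw (identity-features) baseline.")
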