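"""A miniature power study: burden vs score-based tests under two regimes.

Estimates rejection rates at alpha = 0.05 over 50 replicates (the full
study uses 200) for two set-ups: all causal effects positive (Case 1),
where pooling helps, and half negative (Case 2), where the pooled burden
signal cancels and the squared-score tests take over.
"""

from rvassoc import estimate_power

METHODS = ["ols:sum", "ols:asum", "ols:ssu", "ols:f"]

for case, label in [(1, "Case 1: effects all +0.9"),
                    (2, "Case 2: effects +1.2/-1.2 (cancelling)")]:
    df = estimate_power("rv_only", case, n_noncausal=0, methods=METHODS,
                        n_replicates=50, seed=21)
    print(label)
    for _, row in df.iterrows():
        print(f"  {row['method']:9s} power = {row['rejection_rate']:.2f}")
    print()

print("With shared effect direction the Sum test leads; with mixed signs "
      "it collapses toward the 0.05 type-I level while the adaptive Sum "
      "(which flips nominally negative variants) and SSU retain power.")
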