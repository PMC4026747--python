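"""Permutation-calibrated p-value for a penalized-regression test.

Fits TLP-SG with per-dataset AIC tuning, computes the post-selection SSUw
statistic on the variants it keeps, and calibrates the statistic by
re-running the entire pipeline (tuning included) on 100 permutations of
the trait.  The p-value is the fraction of permutations whose statistic
beats the observed one.
"""

from rvassoc import permutation_test, simulate_replicate

geno, trait, config = simulate_replicate("rv_only", case=3, n_noncausal=8,
                                         n=400, seed=3)
print(f"{geno.n} subjects x {geno.k} variants, "
      f"causal effects {config.beta[config.causal_idx].round(1).tolist()}")

res = permutation_test(geno, trait, "tlp_sg", ("one_df", "ssuw"),
                       B=100, seed=42)
for kind, r in res.items():
    print(f"tlp_sg + {kind:6s}: observed T = {r.observed_T:8.3f}, "
          f"permutation p = {r.p_value:.2f}  (B = {r.B}, "
          f"tuned at { {k: float(round(v, 3)) for k, v in r.params.items()} })")

print("\nThe p-value is the fraction of the 100 permutation statistics "
      "that beat the observed one, so it is a multiple of 1/B and can be "
      "exactly 0.  On this draw the penalized test does not reach "
      "significance even though the gene is truly associated — penalized "
      "tests pay for their variable selection and are not uniformly more "
      "powerful than the simple global tests.")
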