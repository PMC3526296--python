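"""Do independent CNE losses exceed a uniform-loss null?

Runs the two mirrored null methods on a dataset where 10% of CNEs carry a
10-fold loss propensity: the exact expectation E_2 = sum f_A f_B N_AB over
valid branch pairs, and the constrained reassignment simulation that
shuffles the observed events onto random eligible CNEs. A z-score and
empirical P-value quantify the excess of doubly lost CNEs.
"""

from cneloss import GeneratorConfig, generate_dataset, loss_frequency_vs_branch_length
from cneloss.pipeline import run_pipeline

ds = generate_dataset(
    GeneratorConfig(seed=23, n_cnes=4000, propensity="hotspot")
)
res = run_pipeline(ds, iterations=2000, seed=99)

s2, s3 = res.summary(2), res.summary(3)
print(f"{res.stats.n_cnes} CNEs, {len(res.events)} loss events")
print(f"observed CNEs lost twice:   {s2.observed}")
print(f"  exact expectation E2:     {res.e2:.2f}")
print(f"  simulation mean +- sd:    {s2.mean:.2f} +- {s2.sd:.2f} "
      f"(max {int(res.null.dist_for(2).max())})")
print(f"  z = {s2.z:.1f}, empirical P = {s2.p_empirical:.2g}")
print(f"observed CNEs lost 3 times: {s3.observed} "
      f"(E3 = {res.e3:.3f}, P = {s3.p_empirical:.2g})")
print("\nThe two null methods agree closely with each other; the observed")
print("count sits above both because the planted hotspot CNEs are far more")
print("likely to be hit twice than a uniform-loss model allows.")

# Loss frequency scales with branch length (neutral substitutions per site):
corr = loss_frequency_vs_branch_length(res.stats, ds.tree)
print(f"\nloss frequency vs branch length: r = {corr['r']:.2f}, "
      f"t = {corr['t']:.1f}, df = {corr['df']}, P = {corr['p']:.2g}")

print("\ntop branch-pair combinations (observed vs expected):")
table = res.null.combination_table(res.e2_per_combo)
table = table[table.k == 2].sort_values("observed", ascending=False).head(5)
print(table.to_string(index=False))
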