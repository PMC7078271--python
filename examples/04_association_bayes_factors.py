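"""Mixed-model associations with bootstrap CIs and Bayes factors.

Fits the random-intercept model for three cognitive outcomes against the
sleep-disturbance composite on a null synthetic cohort (true effect 0)
and prints the paper-style table: standardized beta, cluster-bootstrap
95% CI and p, and the BIC-approximation BF01.
"""

from sleepcog import associate, bf01_interpretation, fit_composite, generate_cohort
from sleepcog.pipeline import render_table

table, truth = generate_cohort(seed=11)
comp = fit_composite(table["psqi"].to_numpy(float), table["ais"].to_numpy(float))
table["sleep_disturbance"] = comp.scores

outcomes = ["counting_span", "wcst_persev_err", "rt_triplet"]
results = associate(table, outcomes=outcomes, B=1000, seed=11)
print(render_table(results))

print(f"\nTrue generating effect was {truth.true_beta['counting_span']}; "
      "every CI spans zero and every BF01 favours the null:")
for _, row in results.iterrows():
    print(f"  {row['outcome']:<18} BF01 = {row['bf01']:6.2f} "
          f"({bf01_interpretation(row['bf01'])})")
print("\nBF01 > 3 means the data are over 3x more likely under 'no"
      " association' than under an association, controlled for age,"
      " gender and morningness, pooled over studies.")
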