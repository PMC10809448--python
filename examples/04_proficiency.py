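"""Proficiency scoring: SNR, relative correlation and recall per batch.

Builds consensus references from a simulated cohort, scores every batch
against them, and prints the ranked leaderboard with performance levels.
"""

from quartetqc import SimConfig, build_all_references, score_batches, simulate

coll, _ = simulate(SimConfig(n_metabolites=100, n_labs=6, seed=4))
refs = build_all_references(coll)
report = score_batches(coll.batches, refs)

cols = ["snr_db", "rc", "recall", "total_score", "rank", "level"]
print(report.table[cols].round(3).to_string())
print()
print("Each metric is min-max scaled to [0, 10] across the cohort; the")
print("total score is their mean, and levels follow the cohort quartiles")
print("(top quartile Great ... bottom quartile Bad).")
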