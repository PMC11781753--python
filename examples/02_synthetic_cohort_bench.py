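"""Classifier bench on a synthetic cohort with a planted complexity gap.

Simulates 13 "elite" and 12 "expert" athletes under the foam-surface
condition (30 s at 100 Hz), extracts both feature sets for the radial CoP
excursion (COPLen), and cross-validates the Ranking Forest on each.  The
groups are matched in sway magnitude and differ only in signal
irregularity, so the complexity features should separate them while the
moment features hover near chance.
"""

from cmci import SimConfig, build_feature_table, cross_validate, generate_cohort

cfg = SimConfig(conditions=("T2",), group_complexity_gap=0.8, seed=7)
recordings, _ = generate_cohort(cfg)
print(f"simulated {len(recordings)} recordings "
      f"({cfg.n_elite} elite + {cfg.n_expert} expert, condition T2)")

for feature_set in ("cmci", "time_domain"):
    table = build_feature_table(recordings, feature_set=feature_set,
                                variables=("COPLen",))
    res = cross_validate(table, classifier="ranking_forest", k=10, seed=1)
    print(f"{feature_set:>11}: CV mean AUC = {res.cv_mean_auc:.3f}, "
          f"sensitivity = {res.cv_mean_sensitivity:.2f}, "
          f"specificity = {res.cv_mean_specificity:.2f}")

print("\nThe complexity features reach an AUC near 1 while the time-domain "
      "moments lag far behind: the planted gap lives in irregularity, not "
      "magnitude.")
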