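"""Simulate toddler sessions and score them.

Scores per session: AccD (prepotent minus inhibitory %correct; higher =
poorer inhibition), adjusted AccD (AccD / prepotent proportion correct) and
RTD (median correct inhibitory RT minus median correct prepotent RT).
Sessions with prepotent accuracy not strictly above 60% are flagged excluded.
"""

from ecitt import get_profile, score_session, scores_frame, simulate_cohort

members = simulate_cohort([get_profile("toddler_18m"), get_profile("toddler_30m")],
                          n_per_profile=40, seed=1)
frame = scores_frame([score_session(m.session) for m in members])

summary = frame[frame["included"]].groupby("group")[
    ["pct_correct_prepotent", "pct_correct_inhibitory", "accd", "rtd"]
].mean().round(1)
print(summary)
print(f"\nexcluded sessions: {(~frame['included']).sum()} of {len(frame)}")
# Expect 18-month inhibitory accuracy near 63% vs >90% prepotent (large AccD),
# and near-ceiling 30-month performance (small AccD); RTD positive at both ages.
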