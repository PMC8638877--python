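"""Lifespan pattern on the fast-paced task: U-shaped age trend.

Children, young adults and older adults are simulated on the 96-trial adult
version; inhibition scores are regressed on age with and without a quadratic
term.  Inhibitory control peaks in young adulthood, so the quadratic model
should win for RTD across the lifespan.
"""

from ecitt import (
    ECITT_A,
    age_trend,
    get_profile,
    score_session,
    scores_frame,
    simulate_cohort,
    welch_t,
)

profiles = [get_profile(l) for l in ("child_8y", "young_adult", "older_adult")]
members = simulate_cohort(profiles, 30, seed=9, variant=ECITT_A)
frame = scores_frame([score_session(m.session) for m in members])
frame = frame[frame["included"]]

print(frame.groupby("group")[["accd", "rtd"]].mean().round(2))

child_rtd = frame.loc[frame["group"] == "child_8y", "rtd"]
adult_rtd = frame.loc[frame["group"] == "young_adult", "rtd"]
t = welch_t(child_rtd, adult_rtd)
print(f"\nchild vs young-adult RTD: t({t.df:.1f}) = {t.t:.2f}, "
      f"p = {t.p:.4f}, d = {t.d:.2f}")

res = age_trend(frame["age_months"], frame["rtd"])
print(f"RTD ~ age: linear R2 = {res.linear_r2:.3f}; adding age^2: "
      f"delta R2 = {res.delta_r2:.3f}, F = {res.f_increment:.1f}, "
      f"p = {res.p_increment:.2g}")
# A significant quadratic increment with a positive age^2 coefficient is the
# U shape: worse inhibition at both ends of the lifespan.
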