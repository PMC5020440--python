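"""The four-model regression ladder on a rank-generated cohort.

Judgments are generated from relative rank alone; the ladder then shows
the signature of a rank mechanism: BrAC predicts on its own (Model 1,
as a proxy for rank), rank predicts better (Model 2), and when both are
entered jointly with the group-mean-distance control (Model 3) only the
rank coefficient's confidence interval excludes zero.  Model 4 confirms
this is robust to covariate adjustment.
"""

import ranknorms as rn

pool = rn.generate_pool(rn.CohortConfig(), seed=7)
mech = rn.JudgementMechanism("rank", intercept=2.78, slope=3.42, noise_sd=1.75)
judgements = rn.generate_judgements(pool, mech, n_sub=400, seed=8,
                                    outcomes=("judge_drunk",))
frame = rn.build_analysis_frame(judgements)

for model_id in (1, 2, 3, 4):
    fit = rn.fit_model(frame, rn.ModelSpec(model_id, "judge_drunk"))
    print(f"\nModel {model_id}  (n={fit.n_used}, R2={fit.r_squared:.3f})")
    for name, row in fit.params.iterrows():
        print(f"  {name:<22} b={row['b']:>8.3f} "
              f"[{row['ci_low']:>7.3f}, {row['ci_high']:>7.3f}] {row['stars']}")
    if len(fit.vif):
        print("  VIF: " + ", ".join(f"{k}={v:.1f}" for k, v in fit.vif.items()))

rho = rn.spearman_rho(frame["brac"], frame["rank"])
print(f"\nSpearman rho(BrAC, rank) = {rho:.3f} — the two are strongly but not")
print("perfectly collinear, which is what lets Model 3 tell the mechanisms apart:")
print("the rank CI excludes 0 while the BrAC CI covers 0.")
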