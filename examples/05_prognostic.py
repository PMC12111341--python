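"""Cox prognostics on the genes composing the reversal pairs.

A synthetic tumor cohort carries planted log-hazard effects (beta = +0.7 on
one gene, -0.5 on another).  The multivariate Cox fit recovers the betas,
the median split of the risk score separates survival curves, and Harrell's
C summarises discrimination.
"""

from reopair import prognostic, reo, synthetic

cfg_expr = synthetic.SyntheticExprConfig(
    n_genes=9, n_planted_pairs=0, n_tumor=300, n_normal=1, seed=4
)
expr = synthetic.gen_labeled_expression(cfg_expr).class_matrix(reo.TUMOR)
cfg_surv = synthetic.SyntheticSurvivalConfig(
    n_samples=300, betas={"G0000": 0.7, "G0001": -0.5},
    censor_rate=0.045, seed=4,
)
survival = synthetic.gen_survival(cfg_surv, expr)
print(f"events observed: {int(survival['event'].sum())}/300")

uni = prognostic.fit_cox(expr, survival, mode="univariate")
print("\nunivariate Cox (per gene):")
print(uni.table.round(4).to_string())

multi = prognostic.fit_cox(expr, survival, mode="multivariate")
print(f"\nmultivariate C-index: {multi.c_index:.3f}")
groups = prognostic.risk_stratify(multi)
curves, stat, p = prognostic.km_logrank(groups, survival)
print(f"median-split log-rank chi2 = {stat:.2f}, p = {p:.3g}")
print("high-risk group size:", (groups == "high").sum())

corr = prognostic.coexpression(expr)
print("\nSpearman co-expression of the first 3 genes:")
print(corr.iloc[:3, :3].round(3).to_string())
# Expect coef ~ +0.7 / -0.5 on the planted genes, C-index ~ 0.7 and a
# strongly significant log-rank split.
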