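"""Cross-sectional resilience-factor battery with covariate screening.

Each baseline factor is related to baseline SR in its own multiple
regression with fully standardized coefficients; data-driven covariates
first pass a p < .2 likelihood-ratio screen.
"""

from srres import SimConfig, generate_cohort
from srres.prep import screen_covariates
from srres.regression import run_h1
from srres.sr import compute_sr, fit_normative_ols, mahalanobis_outliers

baseline, weekly, _ = generate_cohort(SimConfig(n_participants=558, seed=11))
w0 = weekly[weekly.t == 0].merge(baseline, on="participant_id")

keep, _, _ = mahalanobis_outliers(w0["E"], w0["P"])
line = fit_normative_ols(w0["E"][keep], w0["P"][keep])
data = compute_sr(line, w0, retain_mask=keep).dropna(subset=["sr"])

covariates = screen_covariates(
    data, ["education", "general_health", "diagnosis", "risk_group",
           "opinion_measures"], "cross")
print(f"screened-in covariates (LRT p < .2): {covariates.screened_in}")

table = run_h1(data, covariates)
print("\nstandardized association of each baseline factor with baseline SR")
print("(negative = resilience-promoting; NEU is a risk factor):")
cols = ["predictor", "beta_std", "se", "ci_low", "ci_high", "p", "n"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v: .3f}"))
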