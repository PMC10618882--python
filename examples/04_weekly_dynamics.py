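"""Within-person weekly dynamics: contemporaneous and lagged models.

Weekly factor modes are split into a person mean (between-person part)
and weekly deviations (within-person part); mixed models with a random
intercept and a random slope on the deviation estimate whether weeks in
which a person uses a factor more are also weeks (or followed by weeks)
of lower stressor reactivity.
"""

from srres import SimConfig, generate_cohort
from srres.dynamics import fit_contemporaneous, fit_lagged, icc
from srres.pipeline import bonferroni_threshold
from srres.sr import compute_sr, fit_normative_mixed

_, weekly, _ = generate_cohort(SimConfig(n_participants=300, seed=11))
scored = compute_sr(fit_normative_mixed(weekly), weekly)

alpha_primary = bonferroni_threshold(0.05, 2)
print(f"primary lagged hypotheses tested at alpha = {alpha_primary}\n")
print(f"{'factor':>6} {'ICC':>5} {'within b':>9} {'p':>8} {'lagged b':>9} {'p':>8}")
for rf in ("PA", "PAC", "GSE", "PSS", "BC"):
    col = f"rf_{rf}"
    cont = fit_contemporaneous(scored, col, "sr")
    lag = fit_lagged(scored, col, "sr")
    i = icc(scored[scored.t >= 1], col)["icc"]
    print(f"{rf:>6} {i:5.2f} {cont.within_beta:9.3f} {cont.within_p:8.3f} "
          f"{lag.within_beta:9.3f} {lag.within_p:8.3f}")

print("\nICCs near the generator's variance-ratio targets mean most mode"
      "\nvariance is stable between persons; contemporaneous within-person"
      "\neffects appear where the generator injects them, lagged ones do not.")
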