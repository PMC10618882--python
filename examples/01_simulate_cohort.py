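"""Generate a synthetic weekly stress-survey cohort with known ground truth.

Builds a 300-person cohort (baseline + 5 weekly follow-ups), prints the
data layout and the generating quantities every downstream estimator is
later judged against.
"""

from srres import SimConfig, generate_cohort

config = SimConfig(n_participants=300, seed=11)
baseline, weekly, truth = generate_cohort(config)

print(f"baseline table: {baseline.shape[0]} participants x {baseline.shape[1]} columns")
print(f"weekly table:   {weekly.shape[0]} retained participant-weeks")
print(f"rows per assessment index:\n{weekly.groupby('t').size().to_string()}\n")
print(f"generating E-P line: P = {truth.ep_intercept} + {truth.ep_slope} * E")
print("\nper-factor generating effects (symptom units per SD of the latent):")
print(truth.effects.to_string(index=False, float_format=lambda v: f"{v: .3f}"))
print(f"\nmediation chain: {truth.mediation}")

# The columns are raw survey items: 40 stressor severities (0-5), 12
# symptom items (0-3), weekly mode scores for the five weekly factors.
# E and P are the scored exposure and symptom totals for convenience.
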