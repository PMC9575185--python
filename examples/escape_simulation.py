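"""Simulate escape from drug-induced G1 arrest and resistant-colony timing.

A drug-tolerant culture sits in G1 arrest; cells sporadically escape into
a cell cycle, each completed S phase carrying a small chance of acquiring
a resistance amplification. The run shows (a) the nucleoside-labelling
laws used to measure the escape rate, and (b) the long-stasis /
sudden-colony phenomenology, including how a CDK4/6-inhibitor factor on
the escape rate delays resistance.
"""
import math

import dtpescape as d

# continuous labelling: with escape rate ln2/11 per day, half the
# population has entered S phase by day 11
params = d.EscapeParams(n0=20_000, lambda_escape=math.log(2) / 11)
analytic, simulated = d.cumulative_label_fraction(params, t_days=11.0, seed=1)
print(f"continuous label, day 11: simulated {simulated:.3f} vs "
      f"analytic 1 - e^(-lambda t) = {analytic:.3f}")

# a short pulse labels the cells in S during the window
x = (1 - math.sqrt(1 - 4 * 0.049)) / 2
pulse_params = d.EscapeParams(n0=20_000, lambda_escape=x / 0.5, t_S=8.0,
                              p_death_on_cycle=0.5)
frac = d.pulse_label_fraction(pulse_params, pulse_start=1.0, pulse_len=4.0, seed=2)
print(f"4-h pulse at 24 h: {100 * frac:.2f}% labelled "
      "(escape rate calibrated to 4.9%)")

# time to first resistant colony, with and without a CDK4/6i factor
base = dict(n0=10_000, lambda_escape=0.01, p_resist=2e-4,
            death_rate=0.01, p_death_on_cycle=0.5, resistant_doubling=24.0)
for label, factor in (("drug alone", 1.0), ("drug + CDK4/6i", 0.1)):
    p = d.EscapeParams(**base, cdk46i_factor=factor)
    out = d.simulate_culture(p, horizon_weeks=26, seed=5,
                             stop_at_first_colony=True)
    when = f"week {out.t_colony:.1f}" if out.resistant else "none by week 26"
    print(f"{label:>15}: {out.n_escape_events:5d} escape events, "
          f"first colony (>=50 cells): {when}")
print("\nSuppressing escape from arrest (factor 0.1) delays or prevents the")
print("sudden appearance of a resistant colony, while the arrested bulk")
print("population stays outwardly static throughout.")
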