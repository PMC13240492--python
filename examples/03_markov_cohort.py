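"""Run the four-state one-day-cycle cohort model for one strategy.

1000 patients start with an open ulcer; each day they can heal, lose the
limb, die, or (once healed) recur.  Costs are per-day state costs plus a
one-off intervention cost; QALYs accrue as annual utility / 365.
"""

import eswtcea as e

dataset = e.generate_trial(e.TrialConfig())
fit = e.fit_weibull_ph(dataset)
model = e.DecisionModel(fit=fit)

for strategy in ("standard", "high_dose"):
    trace = model.evaluate_strategy(strategy)
    summary = e.trace_summary(trace)
    print(f"{strategy:>9}: cost £{trace.cum_cost:.2f}  "
          f"QALYs {trace.cum_qaly:.3f}  "
          f"days open {summary.loc[0, 'days_open']:.0f}, "
          f"healed {summary.loc[0, 'days_healed']:.0f}")
print("-> per-patient one-year totals; the cohort of "
      f"{model.cohort_size} scales these by {model.cohort_size}")

trace = model.evaluate_strategy("high_dose")
print("\nfirst cycles of the trace (proportions of the cohort):")
print(trace.to_frame().head(3).round(5))
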