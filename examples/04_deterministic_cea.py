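"""Deterministic base-case analysis with the dominance decision rule.

A strategy dominates when it yields more QALYs at lower cost than every
comparator — then no incremental cost-effectiveness ratio is needed.
"""

import eswtcea as e

dataset = e.generate_trial(e.TrialConfig())
fit = e.fit_weibull_ph(dataset)
model = e.DecisionModel(fit=fit)

result = e.deterministic_analysis(model)
print(result.table.round(3))
print("-> d_cost/d_qaly are increments vs standard care; a 'dominant' "
      "label means cheaper AND more effective")

high = result.table.loc["high_dose"]
print(f"\nincremental NMB of high dose at £20 000/QALY: "
      f"£{e.nmb(high['d_qaly'], high['d_cost']):.2f}")
print("-> 20 000 x QALY gain minus the cost increment")
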