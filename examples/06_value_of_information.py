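"""Value-of-information analysis: EVPI and nested-simulation EVPPI.

EVPI is the expected opportunity loss of deciding under current
uncertainty — the ceiling worth of further research.  EVPPI isolates the
value of learning one parameter group perfectly (here with reduced loop
sizes so the example runs in seconds; the full analysis uses 1000 inner
x 250 outer loops).
"""

import eswtcea as e

dataset = e.generate_trial(e.TrialConfig())
fit = e.fit_weibull_ph(dataset)
model = e.DecisionModel(fit=fit)
dists = e.ParameterDistributions.published()

psa = e.run_psa(model, dists, n_iter=1000, seed=1)
evpi = e.evpi_per_patient(psa, threshold=20_000.0)
print(f"per-patient EVPI at £20 000/QALY: £{evpi:.2f}")
for incidence in (50_000, 100_000):
    print(f"population EVPI at {incidence:,}/year incidence: "
          f"£{e.population_evpi(evpi, incidence):,.2f}")
print("-> the most a definitive trial could be worth, per patient and "
      "for one year of UK incidence")

for group in ("high_dose_effect", "state_costs", "state_utilities"):
    est, _ = e.evppi(model, dists, group, outer=50, inner=200, seed=2)
    print(f"EVPPI({group}): £{est:.2f}")
print("-> the value of perfectly learning just that parameter group; "
      "groups that never change the decision are worth £0")
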