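"""Generate a synthetic 74-patient three-arm ESWT pilot trial.

The generator draws Weibull healing times under a proportional-hazards
model with treatment and ulcer covariates, daily Bernoulli amputation and
death as competing events, and right-censoring at six months.
"""

import eswtcea as e

config = e.TrialConfig()            # 74 patients, 1:1:1, 183-day follow-up
dataset = e.generate_trial(config)

print(f"patients: {len(dataset)}  arms: {dataset.arm_counts()}")
events = {ev: sum(r.event == ev for r in dataset.records)
          for ev in ("healed", "amputated", "died", "censored")}
print(f"events over {config.followup_days} days: {events}")

# cost one patient's resource use at the configured unit prices
patient = dataset.records[0]
prices = {cat: profile["unit_price"]
          for cat, profile in config.resource_profiles.items()}
total = e.price_resource_use(patient.resource_counts, prices)
print(f"patient 0 ({patient.arm}, {patient.event} at day "
      f"{patient.time_days:.0f}): resource use costs £{total:.2f}")
print("-> counts x unit prices summed over podiatry/MDT/GP/nursing/"
      "hospitalisation/dressings")
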