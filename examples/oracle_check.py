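"""Validation: cohort projection versus individual-level microsimulation.

The Markov engine propagates probability mass; the microsimulation draws
200,000 individual patient histories through the identical event logic.
Their means must agree within Monte-Carlo error — a brute-force check
that the cohort algebra is right.  Also shows the mortality-schedule
calibration that produced the shipped schedule fixture.
"""

from cyp2c19_cea import (MicrosimConfig, calibrate_schedule,
                         default_parameters, default_schedule, evaluate,
                         run_microsim)

params = default_parameters()
schedule = default_schedule(params)

cohort = evaluate(params, schedule)
sim = run_microsim(MicrosimConfig(200_000, seed=42, params=params,
                                  schedule=schedule))

for name, arm in (("genetic_testing", cohort.genetic),
                  ("no_testing", cohort.no_testing)):
    s = sim[name]
    zc = (arm.total_cost - s["mean_cost"]) / s["se_cost"]
    zq = (arm.total_qaly - s["mean_qaly"]) / s["se_qaly"]
    print(f"{name}:")
    print(f"  cohort  cost {arm.total_cost:10.2f}  QALY {arm.total_qaly:.4f}")
    print(f"  microsim cost {s['mean_cost']:9.2f} (SE {s['se_cost']:.2f})  "
          f"QALY {s['mean_qaly']:.4f} (SE {s['se_qaly']:.4f})")
    print(f"  z-scores: cost {zc:+.2f}, QALY {zq:+.2f}  (|z| < 3 expected)")

cal = calibrate_schedule(params)
print(f"\nSchedule calibration: scale {cal.scale:.4f}, "
      f"converged={cal.converged}")
print("  per-arm QALY residuals:",
      {k: f"{100*v:+.3f}%" for k, v in cal.residual_qaly.items()})
print("  per-arm cost residuals:",
      {k: f"{100*v:+.2f}%" for k, v in cal.residual_cost.items()})
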