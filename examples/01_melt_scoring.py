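"""Thermal-shift screening: fit melt curves, score the stabilization.

Simulates a DSF experiment for one protein variant with and without a
stabilizing compound at three concentrations, fits each trace, and applies
the integer scoring rubric (1/2/4 for shifts beyond 1/2/3 degC, best of the
tested concentrations).
"""

from startriage import (
    GroundTruth,
    best_of_concentrations,
    delta_tm,
    fit_melt_curve,
    gen_melt_curve,
)

reference = fit_melt_curve(
    gen_melt_curve(GroundTruth("melt", {"tm": 45.0, "amplitude": 100.0},
                               noise_sd=1.0, seed=0))
)
print(f"no-compound Tm: {reference.tm:.2f} degC")

# a saturating binder: the shift grows with concentration
shifts = {}
for conc, tm_shifted in [(10.0, 46.1), (30.0, 47.3), (100.0, 47.9)]:
    fit = fit_melt_curve(
        gen_melt_curve(GroundTruth("melt", {"tm": tm_shifted, "amplitude": 100.0},
                                   noise_sd=1.0, seed=int(conc)))
    )
    shifts[conc] = delta_tm(fit, reference)
    print(f"{conc:>5.0f} uM: Tm = {fit.tm:.2f} degC, dTm = {shifts[conc]:+.2f} degC")

score = best_of_concentrations(shifts)
print(f"compound score: {score.score} (from best dTm {score.delta_tm:+.2f} degC)")
print("-> a score of 2 means the best shift exceeded 2 degC; scores are summed")
print("   across protein variants to rank screening hits.")
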