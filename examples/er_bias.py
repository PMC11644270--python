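"""Annual-ER bias of ignoring the day/night E₀ asymmetry.

Simulates a year whose nighttime temperature sensitivity is double the
daytime one, then reconstructs annual ecosystem respiration with the
classical nighttime partitioner (one E₀ for the whole diel cycle) and
with the day/night-resolved DT-RH method, comparing both to the
generative truth.
"""

import dnrflux as d
from dnrflux import simulate as S

SEED = 6
truth = d.constant_truth(365, e0_day=150.0, e0_night=300.0, noise_sd=1.0, missing_fraction=0.1, seed=SEED)
drivers = d.generate_drivers(365, latitude=45.0, seed=SEED)
series = d.qc_filter(d.generate_nee(drivers, truth), max_qc=0)
config = d.FitConfig(n_iter=5000, seed=SEED)

dtrh = d.fit_site(series, config=config, epsilon=truth.epsilon)
nt = d.fit_nt_baseline(series, config=config)

er_dtrh = d.estimate_er_series(dtrh.fits, series).er
er_nt = d.estimate_er_series(nt.fits, series).er
er_true = S.true_er(series, truth)
covered = er_dtrh.notna() & er_nt.notna()
to_gc = series.step_seconds * 12e-6  # µmol CO2 -> g C per step

truth_sum = er_true[covered].sum() * to_gc
nt_sum = er_nt[covered].sum() * to_gc
dtrh_sum = er_dtrh[covered].sum() * to_gc
print(f"true annual ER            : {truth_sum:7.0f} g C m⁻²")
print(f"NT (single E0) estimate   : {nt_sum:7.0f} g C m⁻²  ({100 * (nt_sum - truth_sum) / truth_sum:+.1f} %)")
print(f"DT-RH (diel E0) estimate  : {dtrh_sum:7.0f} g C m⁻²  ({100 * (dtrh_sum - truth_sum) / truth_sum:+.1f} %)")
print(
    "\nThe nighttime method carries the steep nighttime temperature response"
    "\ninto the warmer daytime hours and overestimates annual respiration;"
    "\nresolving E0 by day and night removes most of that bias."
)
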