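"""Seasonal statistics of the day/night E₀ discrepancy on a full synthetic year.

Uses the default seasonal scenario (daytime sensitivity peaks in summer
while nighttime sensitivity dips, as mid-latitude towers show), fits the
DT-RH model in moving windows, and prints the monthly ΔE₀ curve with its
seasonal coefficient of variation and amplitude.
"""

import dnrflux as d

SEED = 5
truth = d.seasonal_truth(365, latitude=45.0, noise_sd=1.0, missing_fraction=0.1, seed=SEED)
drivers = d.generate_drivers(365, latitude=45.0, seed=SEED)
series = d.qc_filter(d.generate_nee(drivers, truth), max_qc=0)

result = d.fit_site(series, config=d.FitConfig(n_iter=5000, seed=SEED), epsilon=truth.epsilon)
monthly = d.monthly_aggregate(result.fits)
truth_monthly = truth.params.resample("ME").mean()

print("month   ΔE0 est   ΔE0 truth")
for _, row in monthly.iterrows():
    tr = truth_monthly.iloc[int(row["month"]) - 1]
    print(f"  {int(row['month']):2d}     {row['delta_e0']:5.2f}     {tr['e0_night'] / tr['e0_day']:5.2f}")

print(f"\nseasonal CV of E0,day   : {d.seasonal_cv(monthly, 'day'):5.1f} %")
print(f"seasonal CV of E0,night : {d.seasonal_cv(monthly, 'night'):5.1f} %")
print(f"seasonal CV of ΔE0      : {d.seasonal_cv(monthly, 'delta'):5.1f} %")
print(f"ΔE0 seasonal amplitude  : {d.seasonal_amplitude(monthly):5.2f}")
print(
    "\nThe CV (sd/mean of the monthly values, %) and the amplitude"
    "\n(max − min monthly ΔE0) quantify how strongly the day/night"
    "\nasymmetry varies through the year; the dip toward 1 in summer and"
    "\nthe winter excess are the scenario's prescribed structure."
)
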