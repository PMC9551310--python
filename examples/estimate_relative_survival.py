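"""Period-analysis relative survival, window by window.

Builds annual risk sets for three calendar windows (with left truncation:
patients diagnosed before a window enter at the follow-up time they reach
when the window opens), and prints 5-year relative survival — observed
survival by the actuarial life-table method over Ederer II expected
survival — with Greenwood standard errors.
"""

from periodsurv import (
    AnalysisWindow,
    SimulationSpec,
    build_risk_sets,
    compute_estimate,
    simulate_cohort_frame,
    simulate_lifetable,
    true_relative_survival,
)

spec = SimulationSpec(seed=20240517)
lifetable = simulate_lifetable(spec)
cohort = simulate_cohort_frame(spec, lifetable)

print("window      R5 (%)  ± se   truth (%)")
for p, (start, end) in enumerate(spec.periods[1:], start=2):
    window = AnalysisWindow("period", start, end, k=5)
    risk_sets = build_risk_sets(cohort, window, lifetable)
    est = compute_estimate(risk_sets)
    truth = true_relative_survival(spec, p, 5)
    print(f"{window.label}   {100 * est.R[4]:5.1f}  ± {100 * est.se_R[4]:.1f}"
          f"   {100 * truth:.1f}")

print()
print("Each row conditions on person-time inside one calendar window, so the")
print("latest row reflects current care rather than decade-old diagnoses.")
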