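"""Dixon's Q outlier screening on the control-group brain burden.

The generator can plant a single high brain value in the control group
(0.095 %RD against siblings near 0.063).  Dixon's Q for the suspect extreme
is (0.095-0.065)/(0.095-0.060) = 0.857, above the two-tailed 95% critical
value of 0.829 for n = 4, so the screen removes it and the corrected group
mean drops back to 0.063 +/- 0.003 %RD.
"""

from gdchelate import (
    GeneratorConfig,
    dixon_q_test,
    generate_balance_study,
    percent_recovered_dose,
    summarize_groups,
)

study = generate_balance_study(GeneratorConfig(
    seed=0, sd_scale=0.0, brain_outlier=True, recovery_range=(0.95, 0.95),
))
prd = percent_recovered_dose(study)
brain = prd[(prd.group == "control") & (prd.compartment == "brain")]
values = brain.percent_rd.to_numpy()
print("control brain %RD:", [round(v, 4) for v in values])

res = dixon_q_test(values, confidence=0.95)
print(f"Dixon's Q = {res.Q:.3f} vs critical {res.critical} (n=4, 95%)")
print("flagged animal:", brain.animal_id.iloc[res.outlier_index])

summaries = summarize_groups(study, dixon_confidence=0.95)
s = summaries["control"]
print(f"corrected brain burden: {s.compartment_mean['brain']:.3f} "
      f"+/- {s.compartment_sd['brain']:.3f} %RD")
brain_removals = [r for r in s.outliers_removed if r[0] == "brain"]
print("brain removal recorded:", brain_removals)
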