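# Scenario: replace the asthma-control effectiveness factor with the
# medication-adherence odds ratio 1.89 (95% CI 1.08-3.30), target states {A, C}.
inherit: base_case.yaml
model:
  effectiveness: medication_adherence
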