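# Scenario: replace the base-case utilities with the alternative set measured
# on the larger sample (states C/D keep their base-case values).
inherit: base_case.yaml
model:
  utility_set: psa_alternative
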