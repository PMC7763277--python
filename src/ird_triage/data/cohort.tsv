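key	value
families_total	42
affected_patients	66
healthy_relatives	113
sequenced_patients	46
ces_tested_families	11
wes_tested_families	5
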