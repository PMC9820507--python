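# Published cohort composition of the 14,364-subject biobank study population.
CLASS	N
T1DM	72
T2DM	2915
NON_DIABETES	11377
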