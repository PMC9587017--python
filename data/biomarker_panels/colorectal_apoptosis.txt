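# 40 miRNAs mediating the apoptosis pathway associated with colorectal cancer
miR-92a
miR-766
miR-21
miR-96
miR-17
miR-100
miR-365
miR-378
miR-18a
miR-125a
miR-125b
miR-10b
miR-200c
miR-217
miR-206
miR-210
miR-23a
miR-520g
miR-129
miR-32
miR-218
miR-195
miR-491
miR-7
miR-148a
miR-708
miR-182
miR-34a
miR-133b
miR-145
miR-143
miR-342
miR-26b
miR-630
miR-135b
miR-196b
miR-22
miR-532
miR-769
miR-20a
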