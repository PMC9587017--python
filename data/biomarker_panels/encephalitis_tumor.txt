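# 27 miRNA biomarkers used to explore the association between
# anti-NMDA receptor encephalitis and tumors
miR-371
miR-372
miR-373
miR-129
miR-103
miR-107
miR-29b
miR-19a
miR-142
miR-26b
miR-421
miR-934
miR-22
miR-34a
miR-214
miR-196a
miR-629
miR-555
miR-657
miR-27a
let-7b
let-7f
let-7a
let-7d
miR-492
miR-150
miR-620
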