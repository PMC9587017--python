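# 25 miRNA biomarkers used to explore the association between
# anti-NMDA receptor encephalitis and vaccination (one name per line)
miR-323
miR-491
miR-654
miR-10a
miR-31
miR-29a
miR-148a
miR-146a
miR-202
miR-342
miR-206
miR-487b
miR-576
miR-555
miR-145
miR-101
miR-19b
miR-33a
miR-155
miR-29b
let-7a
let-7b
let-7c
let-7d
let-7f
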