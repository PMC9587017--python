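# 12 miRNA biomarkers linking major depression and migraine
miR-590
miR-34a
miR-382
miR-30a
miR-375
miR-27a
miR-181a
let-7b
miR-22
miR-155
miR-126
let-7g
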