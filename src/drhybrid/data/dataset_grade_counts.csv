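# Per-source DR-grade counts of the combined fundus training corpus
# (DeepDR + APTOS + EyePACS graded training images).
dataset,grade0,grade1,grade2,grade3,grade4
DeepDR,540,140,234,214,72
APTOS,1805,370,999,193,295
EyePACS,25810,2443,5292,873,708
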