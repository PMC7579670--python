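# Reference confusion matrix of the Hybrid-c fuser on its 5,000-image fundus test set.
# Rows = actual DR grade 0-4, columns = predicted DR grade 0-4.
3565,36,68,1,3
204,87,54,0,1
140,47,540,15,10
7,0,55,54,7
4,1,18,12,71
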