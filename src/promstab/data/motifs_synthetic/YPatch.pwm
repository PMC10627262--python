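# Synthetic idealized pyrimidine-patch frequency matrix (consensus TTCTTCTCCT).
# Constructed for the bundled simulations; supply curated PWMs for real data.
>YPatch
A [  5  5  5  5  5  5  5  5  5  5 ]
C [  5  5 85  5  5 85  5 85 85  5 ]
G [  5  5  5  5  5  5  5  5  5  5 ]
T [ 85 85  5 85 85  5 85  5  5 85 ]
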