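# Synthetic idealized initiator frequency matrix (consensus CTCATTCA).
# Constructed for the bundled simulations; supply curated PWMs for real data.
>Inr
A [  5  5  5 85  5  5  5 85 ]
C [ 85  5 85  5  5  5 85  5 ]
G [  5  5  5  5  5  5  5  5 ]
T [  5 85  5  5 85 85  5  5 ]
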