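# Synthetic EUCAST-style MIC frequency snapshot for S. aureus / dalbavancin.
# This is NOT the EUCAST database export: it is a stand-in distribution with
# the qualitative shape of the public wild-type distribution (mode one to two
# dilutions below the 0.125 mg/L ECOFF, thin upper tail). Replace with a real
# export for substantive use.
mic_mg_per_L,frequency
0.016,0.056
0.03,0.245
0.06,0.543
0.125,0.142
0.25,0.010
0.5,0.002
1,0.001
2,0.001
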