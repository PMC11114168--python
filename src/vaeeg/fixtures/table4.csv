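id,raw,delta,theta,alpha,beta,gamma
Sub01,0.02,0.00,0.00,0.00,0.00,0.00
Sub02,0.30,0.27,0.06,0.00,0.00,0.00
Sub03,0.15,0.01,0.00,0.03,0.00,0.77
Sub04,0.97,0.24,0.28,0.76,0.87,0.61
Sub05,0.64,0.46,0.41,0.33,0.00,0.00
Sub06,0.07,0.49,0.52,0.48,0.76,0.50
Sub07,0.20,0.49,0.42,0.42,0.58,0.65
Sub08,0.00,0.00,0.00,0.00,0.00,0.00
Sub09,0.17,0.42,0.64,0.15,0.04,0.44
Sub10,0.20,0.55,0.36,0.01,0.36,0.06
Sub11,0.06,0.04,0.02,0.03,0.01,0.01
Sub12,0.06,0.35,0.16,0.21,0.00,0.00
Sub13,0.26,0.15,0.89,0.30,0.30,0.82
Sub14,0.13,0.47,0.25,0.02,0.02,0.03
Sub15,0.05,0.11,0.02,0.01,0.01,0.01
Sub16,0.37,0.09,0.10,0.13,0.13,0.01
Sub17,0.00,0.00,0.00,0.00,0.00,0.00
Sub18,0.63,0.52,0.60,0.48,0.48,0.18
Sub19,0.99,0.09,0.29,0.45,0.32,0.31
Sub20,0.08,0.02,0.01,0.01,0.01,0.02
Sub21,0.03,0.06,0.01,0.01,0.01,0.00
Sub22,0.02,0.00,0.01,0.00,0.00,0.00
Sub23,0.01,0.55,0.58,0.71,0.71,0.00
Sub24,0.72,0.92,0.31,0.33,0.33,0.07
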