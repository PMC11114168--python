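id,sex,MA_T vs VA_T,MA1 vs VA1,MA1 vs VA2,MA1 vs VA3,MA1 vs VA4,MA2 vs VA1,MA2 vs VA2,MA2 vs VA3,MA2 vs VA4
Sub01,M,0.02,0.02,0.56,0.22,0.12,0.04,0.05,0.77,0.04
Sub02,F,0.30,0.08,0.01,0.72,0.33,0.35,0.41,0.12,0.07
Sub03,M,0.15,0.01,0.56,0.03,0.04,0.28,0.19,0.03,0.60
Sub04,M,0.97,0.38,0.31,0.31,0.81,0.21,0.60,0.73,0.56
Sub05,F,0.64,0.27,0.65,0.69,0.24,0.27,0.80,0.31,0.83
Sub06,F,0.07,0.00,0.04,0.09,0.22,0.00,0.04,0.09,0.34
Sub07,M,0.02,0.03,0.05,0.05,0.07,0.03,0.00,0.01,0.06
Sub08,M,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
Sub09,M,0.17,0.42,0.37,0.48,0.40,0.45,0.12,0.08,0.45
Sub10,F,0.20,0.31,0.23,0.47,0.33,0.29,0.30,0.03,0.33
Sub11,F,0.06,0.10,0.16,0.04,0.00,0.28,0.44,0.00,0.08
Sub12,M,0.06,0.04,0.07,0.06,0.12,0.04,0.03,0.03,0.88
Sub13,F,0.26,0.39,0.34,0.45,0.08,0.36,0.33,0.46,0.08
Sub14,M,0.17,0.06,0.03,0.64,0.13,0.06,0.03,0.42,0.18
Sub15,M,0.16,0.03,0.57,0.00,0.03,0.17,0.33,0.04,0.28
Sub16,F,0.10,0.10,0.15,0.12,0.13,0.10,0.16,0.13,0.16
Sub17,F,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
Sub18,M,0.57,0.19,0.32,0.35,0.44,0.76,0.94,0.94,0.83
Sub19,F,0.33,0.69,0.65,0.68,0.68,0.14,0.13,0.11,0.11
Sub20,F,0.70,0.04,0.83,0.08,0.08,0.03,0.04,0.79,0.50
Sub21,F,0.03,0.03,0.04,0.00,0.03,0.25,0.11,0.15,0.05
Sub22,M,0.02,0.03,0.03,0.09,0.03,0.05,0.03,0.09,0.06
Sub23,F,0.01,0.00,0.01,0.02,0.00,0.02,0.01,0.02,0.00
Sub24,M,0.04,0.04,0.04,0.03,0.03,0.66,0.05,0.00,0.09
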