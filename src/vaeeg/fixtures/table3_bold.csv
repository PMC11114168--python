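id,MA_T vs VA_T,MA1 vs VA1,MA1 vs VA2,MA1 vs VA3,MA1 vs VA4,MA2 vs VA1,MA2 vs VA2,MA2 vs VA3,MA2 vs VA4
Sub01,0,0,1,1,1,0,1,1,1
Sub02,1,1,0,1,1,1,1,1,1
Sub03,1,0,1,0,0,1,1,0,1
Sub04,1,1,1,1,1,1,1,1,1
Sub05,1,1,1,1,1,1,1,1,1
Sub06,1,0,0,1,1,0,0,1,1
Sub07,0,0,1,1,1,0,0,0,1
Sub08,0,0,0,0,0,0,0,0,0
Sub09,1,1,1,1,1,1,1,1,1
Sub10,1,1,1,1,1,1,1,1,1
Sub11,1,1,1,0,0,1,1,0,1
Sub12,1,0,1,1,1,0,0,0,1
Sub13,1,1,1,1,1,1,1,1,1
Sub14,1,1,0,1,1,1,0,1,1
Sub15,1,0,1,0,0,1,1,0,1
Sub16,1,1,1,1,1,1,1,1,1
Sub17,0,0,0,0,0,0,0,0,0
Sub18,1,1,1,1,1,1,1,1,1
Sub19,1,1,1,1,1,1,1,1,1
Sub20,1,0,1,1,1,0,0,1,1
Sub21,0,0,0,0,0,1,1,1,1
Sub22,0,0,0,1,0,1,0,1,1
Sub23,0,0,0,0,0,0,0,0,0
Sub24,0,0,0,0,0,1,1,0,1
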