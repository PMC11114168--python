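id,raw,delta,theta,alpha,beta,gamma
Sub01,0,0,0,0,0,0
Sub02,1,1,1,0,0,0
Sub03,1,0,0,0,0,1
Sub04,1,1,1,1,1,1
Sub05,1,1,1,1,0,0
Sub06,1,1,1,1,1,1
Sub07,1,1,1,1,1,1
Sub08,0,0,0,0,0,0
Sub09,1,1,1,1,0,1
Sub10,1,1,1,0,1,1
Sub11,1,0,0,0,0,0
Sub12,1,1,1,1,0,0
Sub13,1,1,1,1,1,1
Sub14,1,1,1,0,0,0
Sub15,1,1,0,0,0,0
Sub16,1,1,1,1,1,0
Sub17,0,0,0,0,0,0
Sub18,1,1,1,1,1,1
Sub19,1,1,1,1,1,1
Sub20,1,0,0,0,0,0
Sub21,0,1,0,0,0,0
Sub22,0,0,0,0,0,0
Sub23,0,1,1,1,1,0
Sub24,1,1,1,1,1,1
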