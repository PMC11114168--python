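id,age,sex,heart_rate,body_temp,vr_history,acu_history
Sub01,23,M,82.5,36.8,N,N
Sub02,23,F,93.5,36.2,Y,N
Sub03,23,M,88.5,36.6,Y,Y
Sub04,23,M,80.0,36.6,Y,N
Sub05,23,F,84.0,36.6,N,N
Sub06,22,F,81.0,36.5,Y,N
Sub07,24,M,58.5,36.7,Y,Y
Sub08,25,M,72.5,36.8,Y,N
Sub09,22,M,68.0,36.7,Y,N
Sub10,23,F,86.5,36.6,N,N
Sub11,25,F,86.5,36.6,N,N
Sub12,26,M,62.5,36.5,N,Y
Sub13,19,F,84.5,36.5,Y,Y
Sub14,21,M,66.5,36.5,Y,Y
Sub15,21,M,77.0,36.6,Y,Y
Sub16,19,F,100.5,36.7,N,Y
Sub17,20,F,100.5,37.1,N,N
Sub18,23,M,79.0,36.4,N,N
Sub19,19,F,79.0,36.8,N,N
Sub20,20,F,91.0,36.5,N,N
Sub21,21,F,82.5,36.5,Y,Y
Sub22,23,M,75.5,35.9,Y,N
Sub23,19,F,70.5,36.2,N,N
Sub24,24,M,72.5,36.5,N,N
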