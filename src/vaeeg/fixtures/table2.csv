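id,MA1,MA2,VA1,VA2,VA3,VA4
Sub01,-,-,-,-,-,-
Sub02,-,0.07,-,-,-,-
Sub03,-,-,-,-,-,-
Sub04,-,-,-,-,-,-
Sub05,-,-,-,-,-,-
Sub06,-,-,-,-,-,-
Sub07,-,-,-,-,-,-
Sub08,-,-,-,-,-,-
Sub09,0.19,-,-,-,-,-
Sub10,-,0.14,-,0.58,-,-
Sub11,-,-,-,-,-,-
Sub12,-,-,-,-,0.49,-
Sub13,-,-,-,-,-,-
Sub14,-,-,-,-,-,-
Sub15,-,-,-,-,0.33,0.28
Sub16,-,-,-,-,-,-
Sub17,-,-,-,-,-,0.10
Sub18,-,-,-,-,-,-
Sub19,-,-,-,-,-,-
Sub20,-,-,-,-,-,-
Sub22,-,-,-,-,-,0.09
Sub23,-,-,-,-,0.24,-
Sub24,-,-,-,-,-,-
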