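# Synthetic exhaustion gene list (stand-in; replace with a published signature)
EXG001
EXG002
EXG003
EXG004
EXG005
EXG006
EXG007
EXG008
EXG009
EXG010
EXG011
EXG012
EXG013
EXG014
EXG015
EXG016
EXG017
EXG018
EXG019
EXG020
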