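# Constitutively expressed reference genes used to calibrate the
# fold-change threshold for differential-expression calls.
RPS13
RPS20
RPL30
RPL13A
RPL9
SRP14
RPL24
RPL22
RPS29
RPS16
RPL4
RPL6
OAZ1
RPS12
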