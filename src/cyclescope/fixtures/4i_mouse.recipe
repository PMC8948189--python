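PORT: blocking
PUMP: 500
HOLD: 60
PORT: primary_1
PUMP: 500
HOLD: 120
PORT: secondary_1
PUMP: 500
HOLD: 120
PORT: imaging
PUMP: 500
IMAG: 1
PORT: elution
PUMP: 500
HOLD: 10
PORT: elution
PUMP: 500
HOLD: 10
PORT: elution
PUMP: 500
HOLD: 10
PORT: elution
PUMP: 500
HOLD: 10
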