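# Racket-to-body attachment for a left-handed grip.
RKT_HANDLE LWRA
RKT_HANDLE LWRB
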