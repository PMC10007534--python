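# Default racket-to-body attachment for a right-handed grip: the bottom-of-
# handle marker connects to the dominant hand's wrist-bar markers.
RKT_HANDLE RWRA
RKT_HANDLE RWRB
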