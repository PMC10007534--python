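# Seven-marker tennis racket model: one at the top of the head, two on each
# side of the head, one at the bottom of the head, one at the bottom of the
# handle.
RKT_TOP racket
RKT_SIDE_L1 racket
RKT_SIDE_L2 racket
RKT_SIDE_R1 racket
RKT_SIDE_R2 racket
RKT_HEAD_BOT racket
RKT_HANDLE racket
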