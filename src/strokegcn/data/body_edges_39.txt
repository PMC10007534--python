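# Default anatomical edge table for the 39-marker full-body model.
# One unordered pair per line.  Markers within a segment are chained and
# segments are joined at shared landmarks.  The published description of the
# classifier does not print its adjacency; this table is the package's own
# reproducible construction and can be replaced by any file of the same
# format.
# head ring
LFHD RFHD
LFHD LBHD
RFHD RBHD
LBHD RBHD
# head to spine
LBHD C7
RBHD C7
# torso
C7 T10
C7 CLAV
CLAV STRN
STRN T10
C7 RBAK
RBAK T10
# shoulder girdle
C7 LSHO
C7 RSHO
CLAV LSHO
CLAV RSHO
# left arm chain
LSHO LUPA
LUPA LELB
LELB LFRM
LFRM LWRA
LFRM LWRB
LWRA LWRB
LWRA LFIN
LWRB LFIN
# right arm chain
RSHO RUPA
RUPA RELB
RELB RFRM
RFRM RWRA
RFRM RWRB
RWRA RWRB
RWRA RFIN
RWRB RFIN
# torso to pelvis
T10 LPSI
T10 RPSI
STRN LASI
STRN RASI
# pelvis ring
LASI RASI
LASI LPSI
RASI RPSI
LPSI RPSI
# left leg chain
LASI LTHI
LTHI LKNE
LKNE LTIB
LTIB LANK
LANK LHEE
LANK LTOE
LHEE LTOE
# right leg chain
RASI RTHI
RTHI RKNE
RKNE RTIB
RTIB RANK
RANK RHEE
RANK RTOE
RHEE RTOE
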