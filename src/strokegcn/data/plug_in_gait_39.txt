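# Plug-in Gait full-body marker set (39 markers), canonical order.
# label  segment
LFHD head
RFHD head
LBHD head
RBHD head
C7 torso
T10 torso
CLAV torso
STRN torso
RBAK torso
LSHO left_arm
LUPA left_arm
LELB left_arm
LFRM left_arm
LWRA left_arm
LWRB left_arm
LFIN left_arm
RSHO right_arm
RUPA right_arm
RELB right_arm
RFRM right_arm
RWRA right_arm
RWRB right_arm
RFIN right_arm
LASI pelvis
RASI pelvis
LPSI pelvis
RPSI pelvis
LTHI left_leg
LKNE left_leg
LTIB left_leg
LANK left_leg
LHEE left_leg
LTOE left_leg
RTHI right_leg
RKNE right_leg
RTIB right_leg
RANK right_leg
RHEE right_leg
RTOE right_leg
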