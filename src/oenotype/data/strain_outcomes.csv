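strain_id,fermentation_capacity,sensory_group,preliminary_group,validated
S1,yes,B,green,yes
S2,no,none,yellow,yes
S3,no,none,yellow,yes
S4,no,none,yellow,yes
S5,yes,B,grey,yes
S6,yes,A,grey,yes
S7,no,none,green,yes
S8,no,none,grey,yes
S9,yes,C,yellow,yes
S10,yes,A,green,yes
S11,yes,D,pink,yes
S12,yes,A,grey,yes
S13,no,none,green,yes
S14,yes,B,grey,yes
S15,yes,D,pink,yes
S16,yes,A,grey,yes
S17,yes,C,yellow,yes
S18,yes,A,green,yes
S19,no,none,grey,yes
S20,yes,B,green,yes
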