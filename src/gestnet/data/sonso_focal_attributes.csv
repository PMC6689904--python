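id,sex,age,reproductive_status,mother_id,observation_minutes
BB,male,21,not_applicable,,516
HW,male,15,not_applicable,,1030
KT,male,15,not_applicable,,1026
KU,female,29,pregnant,,910
KW,female,27,nursing,,510
ML,female,33,cycling,,1118
MS,male,17,not_applicable,,524
NB,female,46,cycling,,500
NK,male,26,not_applicable,,582
RH,female,43,nursing,,1038
SQ,male,17,not_applicable,,554
ZM,female,40,cycling,,710
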