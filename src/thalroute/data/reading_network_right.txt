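Frontal_Inf_Tri_R
Frontal_Inf_Oper_R
Insula_R
Fusiform_R
SupraMarginal_R
Angular_R
Heschl_R
Temporal_Sup_R
Temporal_Mid_R
Temporal_Inf_R
Temporal_Pole_Sup_R
Rolandic_Oper_R
Thalamus_R
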