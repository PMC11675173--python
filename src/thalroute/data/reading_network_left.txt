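Frontal_Inf_Tri_L
Frontal_Inf_Oper_L
Insula_L
Fusiform_L
SupraMarginal_L
Angular_L
Heschl_L
Temporal_Sup_L
Temporal_Mid_L
Temporal_Inf_L
Temporal_Pole_Sup_L
Rolandic_Oper_L
Thalamus_L
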