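Precentral_L	cortical
Precentral_R	cortical
Frontal_Sup_L	cortical
Frontal_Sup_R	cortical
Frontal_Sup_Orb_L	cortical
Frontal_Sup_Orb_R	cortical
Frontal_Mid_L	cortical
Frontal_Mid_R	cortical
Frontal_Mid_Orb_L	cortical
Frontal_Mid_Orb_R	cortical
Frontal_Inf_Oper_L	cortical
Frontal_Inf_Oper_R	cortical
Frontal_Inf_Tri_L	cortical
Frontal_Inf_Tri_R	cortical
Frontal_Inf_Orb_L	cortical
Frontal_Inf_Orb_R	cortical
Rolandic_Oper_L	cortical
Rolandic_Oper_R	cortical
Supp_Motor_Area_L	cortical
Supp_Motor_Area_R	cortical
Olfactory_L	cortical
Olfactory_R	cortical
Frontal_Sup_Medial_L	cortical
Frontal_Sup_Medial_R	cortical
Frontal_Med_Orb_L	cortical
Frontal_Med_Orb_R	cortical
Rectus_L	cortical
Rectus_R	cortical
Insula_L	cortical
Insula_R	cortical
Cingulum_Ant_L	cortical
Cingulum_Ant_R	cortical
Cingulum_Mid_L	cortical
Cingulum_Mid_R	cortical
Cingulum_Post_L	cortical
Cingulum_Post_R	cortical
ParaHippocampal_L	cortical
ParaHippocampal_R	cortical
Calcarine_L	cortical
Calcarine_R	cortical
Cuneus_L	cortical
Cuneus_R	cortical
Lingual_L	cortical
Lingual_R	cortical
Occipital_Sup_L	cortical
Occipital_Sup_R	cortical
Occipital_Mid_L	cortical
Occipital_Mid_R	cortical
Occipital_Inf_L	cortical
Occipital_Inf_R	cortical
Fusiform_L	cortical
Fusiform_R	cortical
Postcentral_L	cortical
Postcentral_R	cortical
Parietal_Sup_L	cortical
Parietal_Sup_R	cortical
Parietal_Inf_L	cortical
Parietal_Inf_R	cortical
SupraMarginal_L	cortical
SupraMarginal_R	cortical
Angular_L	cortical
Angular_R	cortical
Precuneus_L	cortical
Precuneus_R	cortical
Paracentral_Lobule_L	cortical
Paracentral_Lobule_R	cortical
Heschl_L	cortical
Heschl_R	cortical
Temporal_Sup_L	cortical
Temporal_Sup_R	cortical
Temporal_Pole_Sup_L	cortical
Temporal_Pole_Sup_R	cortical
Temporal_Mid_L	cortical
Temporal_Mid_R	cortical
Temporal_Pole_Mid_L	cortical
Temporal_Pole_Mid_R	cortical
Temporal_Inf_L	cortical
Temporal_Inf_R	cortical
Hippocampus_L	subcortical
Hippocampus_R	subcortical
Amygdala_L	subcortical
Amygdala_R	subcortical
Caudate_L	subcortical
Caudate_R	subcortical
Putamen_L	subcortical
Putamen_R	subcortical
Pallidum_L	subcortical
Pallidum_R	subcortical
Thalamus_L	subcortical
Thalamus_R	subcortical
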