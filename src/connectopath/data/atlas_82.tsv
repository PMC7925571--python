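name	hemisphere	network
left_bankssts	left	default_mode
left_caudalanteriorcingulate	left	ventral_attention
left_caudalmiddlefrontal	left	dorsal_attention
left_cuneus	left	visual
left_entorhinal	left	limbic
left_frontalpole	left	default_mode
left_fusiform	left	visual
left_inferiorparietal	left	default_mode
left_inferiortemporal	left	default_mode
left_insula	left	ventral_attention
left_isthmuscingulate	left	frontoparietal
left_lateraloccipital	left	visual
left_lateralorbitofrontal	left	limbic
left_lingual	left	visual
left_medialorbitofrontal	left	limbic
left_middletemporal	left	default_mode
left_paracentral	left	somatomotor
left_parahippocampal	left	limbic
left_parsopercularis	left	dorsal_attention
left_parsorbitalis	left	default_mode
left_parstriangularis	left	frontoparietal
left_pericalcarine	left	visual
left_postcentral	left	somatomotor
left_posteriorcingulate	left	default_mode
left_precentral	left	dorsal_attention
left_precuneus	left	default_mode
left_rostralanteriorcingulate	left	default_mode
left_rostralmiddlefrontal	left	default_mode
left_superiorfrontal	left	frontoparietal
left_superiorparietal	left	dorsal_attention
left_superiortemporal	left	somatomotor
left_supramarginal	left	ventral_attention
left_temporalpole	left	limbic
left_transversetemporal	left	somatomotor
left_thalamus	left	subcortical
left_caudate	left	subcortical
left_putamen	left	subcortical
left_pallidum	left	subcortical
left_hippocampus	left	subcortical
left_amygdala	left	subcortical
left_accumbens	left	subcortical
right_bankssts	right	default_mode
right_caudalanteriorcingulate	right	ventral_attention
right_caudalmiddlefrontal	right	dorsal_attention
right_cuneus	right	visual
right_entorhinal	right	limbic
right_frontalpole	right	default_mode
right_fusiform	right	visual
right_inferiorparietal	right	default_mode
right_inferiortemporal	right	default_mode
right_insula	right	ventral_attention
right_isthmuscingulate	right	frontoparietal
right_lateraloccipital	right	visual
right_lateralorbitofrontal	right	limbic
right_lingual	right	visual
right_medialorbitofrontal	right	limbic
right_middletemporal	right	default_mode
right_paracentral	right	somatomotor
right_parahippocampal	right	limbic
right_parsopercularis	right	dorsal_attention
right_parsorbitalis	right	default_mode
right_parstriangularis	right	frontoparietal
right_pericalcarine	right	visual
right_postcentral	right	somatomotor
right_posteriorcingulate	right	default_mode
right_precentral	right	dorsal_attention
right_precuneus	right	default_mode
right_rostralanteriorcingulate	right	default_mode
right_rostralmiddlefrontal	right	default_mode
right_superiorfrontal	right	frontoparietal
right_superiorparietal	right	dorsal_attention
right_superiortemporal	right	somatomotor
right_supramarginal	right	ventral_attention
right_temporalpole	right	limbic
right_transversetemporal	right	somatomotor
right_thalamus	right	subcortical
right_caudate	right	subcortical
right_putamen	right	subcortical
right_pallidum	right	subcortical
right_hippocampus	right	subcortical
right_amygdala	right	subcortical
right_accumbens	right	subcortical
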