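region	network
lh_lateraloccipital	Visual
lh_cuneus	Visual
lh_pericalcarine	Visual
lh_lingual	Visual
lh_fusiform	Visual
lh_precentral	Somatomotor
lh_postcentral	Somatomotor
lh_paracentral	Somatomotor
lh_superiortemporal	Somatomotor
lh_transversetemporal	Somatomotor
lh_superiorparietal	DorsalAttention
lh_inferiorparietal	DorsalAttention
lh_supramarginal	VentralAttention
lh_caudalanteriorcingulate	VentralAttention
lh_insula	VentralAttention
lh_caudalmiddlefrontal	VentralAttention
lh_temporalpole	Limbic
lh_entorhinal	Limbic
lh_parahippocampal	Limbic
lh_medialorbitofrontal	Limbic
lh_lateralorbitofrontal	Limbic
lh_rostralmiddlefrontal	Frontoparietal
lh_parsopercularis	Frontoparietal
lh_parstriangularis	Frontoparietal
lh_parsorbitalis	Frontoparietal
lh_superiorfrontal	Default
lh_rostralanteriorcingulate	Default
lh_posteriorcingulate	Default
lh_isthmuscingulate	Default
lh_precuneus	Default
lh_middletemporal	Default
rh_lateraloccipital	Visual
rh_cuneus	Visual
rh_pericalcarine	Visual
rh_lingual	Visual
rh_fusiform	Visual
rh_precentral	Somatomotor
rh_postcentral	Somatomotor
rh_paracentral	Somatomotor
rh_superiortemporal	Somatomotor
rh_transversetemporal	Somatomotor
rh_superiorparietal	DorsalAttention
rh_inferiorparietal	DorsalAttention
rh_supramarginal	VentralAttention
rh_caudalanteriorcingulate	VentralAttention
rh_insula	VentralAttention
rh_caudalmiddlefrontal	VentralAttention
rh_temporalpole	Limbic
rh_entorhinal	Limbic
rh_parahippocampal	Limbic
rh_medialorbitofrontal	Limbic
rh_lateralorbitofrontal	Limbic
rh_rostralmiddlefrontal	Frontoparietal
rh_parsopercularis	Frontoparietal
rh_parstriangularis	Frontoparietal
rh_parsorbitalis	Frontoparietal
rh_superiorfrontal	Default
rh_rostralanteriorcingulate	Default
rh_posteriorcingulate	Default
rh_isthmuscingulate	Default
rh_precuneus	Default
rh_middletemporal	Default
lh_thalamus	Subcortical
lh_caudate	Subcortical
lh_putamen	Subcortical
lh_pallidum	Subcortical
lh_hippocampus	Subcortical
lh_amygdala	Subcortical
lh_accumbens	Subcortical
lh_subthalamic	Subcortical
lh_cerebellum	Subcortical
rh_thalamus	Subcortical
rh_caudate	Subcortical
rh_putamen	Subcortical
rh_pallidum	Subcortical
rh_hippocampus	Subcortical
rh_amygdala	Subcortical
rh_accumbens	Subcortical
rh_subthalamic	Subcortical
rh_cerebellum	Subcortical
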