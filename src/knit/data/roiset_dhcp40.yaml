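# Default 40-ROI profile axis: 20 bilateral region pairs (cortical areas,
# deep grey structures and the cerebellum) ordered pair-wise, left before
# right, temporal -> parietal -> frontal -> occipital -> limbic -> ungrouped.
# This ordering is the package's own convention and is persisted with every
# profile table written against it.
rois:
  - {id: 1, name: anterior_temporal_lobe_medial_L, hemisphere: L, lobe: temporal}
  - {id: 2, name: anterior_temporal_lobe_medial_R, hemisphere: R, lobe: temporal}
  - {id: 3, name: anterior_temporal_lobe_lateral_L, hemisphere: L, lobe: temporal}
  - {id: 4, name: anterior_temporal_lobe_lateral_R, hemisphere: R, lobe: temporal}
  - {id: 5, name: superior_temporal_gyrus_anterior_L, hemisphere: L, lobe: temporal}
  - {id: 6, name: superior_temporal_gyrus_anterior_R, hemisphere: R, lobe: temporal}
  - {id: 7, name: superior_temporal_gyrus_posterior_L, hemisphere: L, lobe: temporal}
  - {id: 8, name: superior_temporal_gyrus_posterior_R, hemisphere: R, lobe: temporal}
  - {id: 9, name: middle_inferior_temporal_gyrus_anterior_L, hemisphere: L, lobe: temporal}
  - {id: 10, name: middle_inferior_temporal_gyrus_anterior_R, hemisphere: R, lobe: temporal}
  - {id: 11, name: middle_inferior_temporal_gyrus_posterior_L, hemisphere: L, lobe: temporal}
  - {id: 12, name: middle_inferior_temporal_gyrus_posterior_R, hemisphere: R, lobe: temporal}
  - {id: 13, name: fusiform_gyrus_anterior_L, hemisphere: L, lobe: temporal}
  - {id: 14, name: fusiform_gyrus_anterior_R, hemisphere: R, lobe: temporal}
  - {id: 15, name: fusiform_gyrus_posterior_L, hemisphere: L, lobe: temporal}
  - {id: 16, name: fusiform_gyrus_posterior_R, hemisphere: R, lobe: temporal}
  - {id: 17, name: parietal_lobe_L, hemisphere: L, lobe: parietal}
  - {id: 18, name: parietal_lobe_R, hemisphere: R, lobe: parietal}
  - {id: 19, name: frontal_lobe_L, hemisphere: L, lobe: frontal}
  - {id: 20, name: frontal_lobe_R, hemisphere: R, lobe: frontal}
  - {id: 21, name: occipital_lobe_L, hemisphere: L, lobe: occipital}
  - {id: 22, name: occipital_lobe_R, hemisphere: R, lobe: occipital}
  - {id: 23, name: cingulate_gyrus_anterior_L, hemisphere: L, lobe: limbic}
  - {id: 24, name: cingulate_gyrus_anterior_R, hemisphere: R, lobe: limbic}
  - {id: 25, name: cingulate_gyrus_posterior_L, hemisphere: L, lobe: limbic}
  - {id: 26, name: cingulate_gyrus_posterior_R, hemisphere: R, lobe: limbic}
  - {id: 27, name: parahippocampal_gyrus_anterior_L, hemisphere: L, lobe: limbic}
  - {id: 28, name: parahippocampal_gyrus_anterior_R, hemisphere: R, lobe: limbic}
  - {id: 29, name: parahippocampal_gyrus_posterior_L, hemisphere: L, lobe: limbic}
  - {id: 30, name: parahippocampal_gyrus_posterior_R, hemisphere: R, lobe: limbic}
  - {id: 31, name: insula_L, hemisphere: L, lobe: limbic}
  - {id: 32, name: insula_R, hemisphere: R, lobe: limbic}
  - {id: 33, name: hippocampus_L, hemisphere: L, lobe: limbic}
  - {id: 34, name: hippocampus_R, hemisphere: R, lobe: limbic}
  - {id: 35, name: amygdala_L, hemisphere: L, lobe: limbic}
  - {id: 36, name: amygdala_R, hemisphere: R, lobe: limbic}
  - {id: 37, name: caudate_nucleus_L, hemisphere: L, lobe: none}
  - {id: 38, name: caudate_nucleus_R, hemisphere: R, lobe: none}
  - {id: 39, name: cerebellum_L, hemisphere: L, lobe: none}
  - {id: 40, name: cerebellum_R, hemisphere: R, lobe: none}
bilateral_pairs:
  - [1, 2]
  - [3, 4]
  - [5, 6]
  - [7, 8]
  - [9, 10]
  - [11, 12]
  - [13, 14]
  - [15, 16]
  - [17, 18]
  - [19, 20]
  - [21, 22]
  - [23, 24]
  - [25, 26]
  - [27, 28]
  - [29, 30]
  - [31, 32]
  - [33, 34]
  - [35, 36]
  - [37, 38]
  - [39, 40]
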