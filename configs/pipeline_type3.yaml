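# Multimodality pipeline: an extra externally produced field from a second
# imaging modality (e.g. T2W, sharper CSF/ventricle contrast) refines the
# alignment after the T1W step (g_subj = g_demo + g_dram + g_m1).
steps:
  - kind: demons_mask
    moving: subj_cranial
    fixed: base_cranial
    tag: g_demo
  - kind: external_field
    path: g_dram_t1.nii.gz
    tag: g_dram
  - kind: external_field
    path: g_m1_t2.nii.gz
    tag: g_m1
regroup:
  mask: subj_wm
  parts: [GM, WM]
evaluate:
  regions: [cranial, brain, ventricle, wm]
inputs:
  baseline_image: baseline_t1.nii.gz
  baseline_mesh: baseline_mesh.vtk
  subj_cranial: subj_cranial.nii.gz
  base_cranial: base_cranial.nii.gz
  subj_wm: subj_wm.nii.gz
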