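# Multi-feature pipeline for grossly changed anatomy (enlarged ventricles,
# lesions): extra Demons feature steps are inserted between the cranial
# anchor and the intensity field, and a final feature step can pull back
# structures displaced by a lesion (g_subj = g_demo + g_f1 + g_f2 + g_dram + g_f3).
steps:
  - kind: demons_mask
    moving: subj_cranial
    fixed: base_cranial
    tag: g_demo
  - kind: demons_feature
    moving: subj_lv
    fixed: base_lv
    tag: g_f1            # enlarged lateral ventricles
  - kind: demons_feature
    moving: subj_cc
    fixed: base_cc
    tag: g_f2            # corpus callosum shape
  - kind: external_field
    path: g_dram.nii.gz
    tag: g_dram
  - kind: demons_feature
    moving: subj_skull_fix
    fixed: base_skull_fix
    tag: g_f3            # drag back structures pushed by the lesion
regroup:
  mask: subj_wm
  parts: [GM, WM]
evaluate:
  regions: [cranial, brain, ventricle, cc, wm]
inputs:
  baseline_image: baseline_t1.nii.gz
  baseline_mesh: baseline_mesh.vtk
  subj_cranial: subj_cranial.nii.gz
  base_cranial: base_cranial.nii.gz
  subj_lv: subj_lv.nii.gz
  base_lv: base_lv.nii.gz
  subj_cc: subj_cc.nii.gz
  base_cc: base_cc.nii.gz
  subj_skull_fix: subj_skull_fix.nii.gz
  base_skull_fix: base_skull_fix.nii.gz
  subj_wm: subj_wm.nii.gz
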