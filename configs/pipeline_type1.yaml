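# Basic two-step pipeline: cranial-mask Demons anchor followed by an
# externally produced intensity-registration field (g_subj = g_demo + g_dram).
# Input names map to files under `inputs:` when run via `headmorph run`.
steps:
  - kind: rigid
    moving: subj_cranial
    fixed: base_cranial
  - kind: demons_mask
    moving: subj_cranial
    fixed: base_cranial
    tag: g_demo
  - kind: external_field
    path: g_dram.nii.gz   # produced by an outside intensity registration tool
    dialect: mm
    tag: g_dram
regroup:
  mask: subj_wm
  parts: [GM, WM]
evaluate:
  regions: [cranial, brain, ventricle, wm]
  units: voxel
inputs:
  baseline_image: baseline_t1.nii.gz
  baseline_mesh: baseline_mesh.vtk
  subj_cranial: subj_cranial.nii.gz
  base_cranial: base_cranial.nii.gz
  subj_wm: subj_wm.nii.gz
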