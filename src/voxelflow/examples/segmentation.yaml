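# Three-tissue segmentation of the synthetic head phantom.
#
# Intensities are rescaled to [0,1]; a band extraction (threshold at 0.7)
# followed by Gaussian smoothing and a second threshold forms the skull mask,
# which gates the brightest class; label codes are then assembled from the
# three disjoint intensity ranges with elementwise nodes:
#   0 background, 1 brain, 2 CSF (cerebrospinal fluid), 3 skull/skin.
# A mid-volume slice of the label map is exported for visual inspection.
nodes:
  - id: head
    kind: head_phantom
    params: {dims: [64, 64, 64], noise_sd: 0.0, seed: 0}
  - id: rescale
    kind: rescale_intensity
  - id: t_brain
    kind: threshold
    params: {t: 0.1}
  - id: t_csf
    kind: threshold
    params: {t: 0.3}
  - id: t_skull
    kind: threshold
    params: {t: 0.7}
  - id: smooth
    kind: gaussian_blur
    params: {sigma: 1.0}
  - id: mask
    kind: threshold
    params: {t: 0.2}
  - id: skull_gated
    kind: elementwise
    params: {op: mul}
  - id: lower_classes
    kind: elementwise
    params: {op: add}
  - id: labels
    kind: elementwise
    params: {op: add}
  - id: label_scale          # 0..3 -> 0..1 for image export
    kind: elementwise
    params: {op: mul, scalar: 0.3333333}
  - id: slice
    kind: extract_slice
    params: {axis: 2, index: 32}
  - id: save_labels
    kind: save_volume
    params: {path: segmentation_labels.vvf}
  - id: save_slice
    kind: save_image
    params: {path: segmentation_slice.png}
edges:
  - head.out -> rescale.in
  - rescale.out -> t_brain.in
  - rescale.out -> t_csf.in
  - rescale.out -> t_skull.in
  - t_skull.out -> smooth.in
  - smooth.out -> mask.in
  - t_skull.out -> skull_gated.a
  - mask.out -> skull_gated.b
  - t_brain.out -> lower_classes.a
  - t_csf.out -> lower_classes.b
  - lower_classes.out -> labels.a
  - skull_gated.out -> labels.b
  - labels.out -> save_labels.in
  - labels.out -> label_scale.a
  - label_scale.out -> slice.in
  - slice.out -> save_slice.in
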