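# Shell (skull) removal via the distance transform, stereo-rendered.
#
# The bright outer shell of the head phantom is thresholded out, the
# Euclidean distance to the nearest shell voxel is computed, and a distance
# threshold keeps only tissue at least `t` voxels away from the shell; the
# original volume multiplied by that mask drops the shell plus a safety
# margin.  The result is rendered as a red/cyan anaglyph.
nodes:
  - id: head
    kind: head_phantom
    params: {dims: [64, 64, 64], noise_sd: 0.0, seed: 0}
  - id: rescale
    kind: rescale_intensity
  - id: shell
    kind: threshold
    params: {t: 0.7}
  - id: dist
    kind: distance_transform
    params: {t: 0.5}
  - id: far_from_shell
    kind: threshold
    params: {t: 3.0}        # distance in voxel units
  - id: stripped
    kind: elementwise
    params: {op: mul}
  - id: render
    kind: volume_renderer
    params:
      mode: translucent
      opacity_scale: 2.0
      stereo: true
      eye_separation: 6.0
      eye: [140.0, 100.0, 80.0]
      target: [32.0, 32.0, 32.0]
      width: 96
      height: 96
  - id: save
    kind: save_image
    params: {path: shell_removed_anaglyph.png}
edges:
  - head.out -> rescale.in
  - rescale.out -> shell.in
  - shell.out -> dist.in
  - dist.out -> far_from_shell.in
  - rescale.out -> stripped.a
  - far_from_shell.out -> stripped.b
  - stripped.out -> render.in
  - render.out -> save.in
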