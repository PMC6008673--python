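# One volume, two renderer nodes viewing it from different perspectives.
# A parameter change on the phantom re-dirties both render branches; each
# node reports its own compute time in the execution log.
nodes:
  - id: sphere
    kind: sphere_phantom
    params: {dims: [48, 48, 48], radius: 14.0, noise_sd: 0.02, seed: 0}
  - id: view_front
    kind: volume_renderer
    params:
      mode: solid
      threshold: 0.5
      eye: [24.0, -60.0, 24.0]
      target: [24.0, 24.0, 24.0]
      width: 80
      height: 80
  - id: view_top
    kind: volume_renderer
    params:
      mode: translucent
      opacity_scale: 1.5
      eye: [24.0, 24.0, 110.0]
      target: [24.0, 24.0, 24.0]
      up: [0.0, 1.0, 0.0]
      width: 80
      height: 80
  - id: save_front
    kind: save_image
    params: {path: sphere_front.png}
  - id: save_top
    kind: save_image
    params: {path: sphere_top.png}
edges:
  - sphere.out -> view_front.in
  - sphere.out -> view_top.in
  - view_front.out -> save_front.in
  - view_top.out -> save_top.in
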