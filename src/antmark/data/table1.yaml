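# Filming metadata for the ten ant-colony sequences (five indoor laboratory
# colonies, five outdoor colonies).  angle_deg is the camera's horizontal tilt;
# the camera's angle of view is 16 deg (horizontal) and 7.5 deg (vertical) for
# every sequence.  body_length_m is the midpoint of the species' published
# body-length range (indoor Camponotus japonicus 7.4-13.8 mm; outdoor species
# 8-10 mm).  body_length_px is an ESTIMATE derived from the printed scene width
# (1920 px / 17 cm indoor, 1280 px / 17 cm outdoor), since per-sequence pixel
# calibration was not published.
Seq0001:
  scene: indoor
  fps: 25
  resolution: [1920, 1080]
  length: 351
  ants: 10
  annotations: 3510
  angle_deg: 0
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.0106
  body_length_px: 120
  species: Japanese arched ants
  entrance: false
Seq0002:
  scene: indoor
  fps: 25
  resolution: [1920, 1080]
  length: 351
  ants: 10
  annotations: 3510
  angle_deg: 0
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.0106
  body_length_px: 120
  species: Japanese arched ants
  entrance: false
Seq0003:
  scene: indoor
  fps: 25
  resolution: [1920, 1080]
  length: 351
  ants: 10
  annotations: 3510
  angle_deg: 0
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.0106
  body_length_px: 120
  species: Japanese arched ants
  entrance: false
Seq0004:
  scene: indoor
  fps: 25
  resolution: [1920, 1080]
  length: 351
  ants: 10
  annotations: 3510
  angle_deg: 0
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.0106
  body_length_px: 120
  species: Japanese arched ants
  entrance: false
Seq0005:
  scene: indoor
  fps: 25
  resolution: [1920, 1080]
  length: 1001
  ants: 10
  annotations: 3510
  angle_deg: 0
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.0106
  body_length_px: 120
  species: Japanese arched ants
  entrance: false
Seq0006:
  scene: outdoor
  fps: 30
  resolution: [1280, 720]
  length: 600
  ants: 73
  annotations: 11178
  angle_deg: 45
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.009
  body_length_px: 68
  species: Carpenter ants
  entrance: true
Seq0007:
  scene: outdoor
  fps: 30
  resolution: [1280, 720]
  length: 677
  ants: 162
  annotations: 25158
  angle_deg: 30
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.009
  body_length_px: 68
  species: Little black ants
  entrance: true
Seq0008:
  scene: outdoor
  fps: 30
  resolution: [1280, 720]
  length: 577
  ants: 133
  annotations: 10280
  angle_deg: 30
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.009
  body_length_px: 68
  species: Carpenter ants
  entrance: true
Seq0009:
  scene: outdoor
  fps: 30
  resolution: [1280, 720]
  length: 526
  ants: 193
  annotations: 27902
  angle_deg: 30
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.009
  body_length_px: 68
  species: Carpenter ants
  entrance: true
Seq0010:
  scene: outdoor
  fps: 30
  resolution: [1280, 720]
  length: 569
  ants: 101
  annotations: 2044
  angle_deg: 0
  height_cm: 30
  view_angle_h_deg: 16
  view_angle_v_deg: 7.5
  body_length_m: 0.009
  body_length_px: 68
  species: Little black ants
  entrance: false
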