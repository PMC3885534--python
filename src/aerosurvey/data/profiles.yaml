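# Built-in camera profiles for the reference RPAS payloads.
# still_photo: 11 MP compact camera in the wing, aimed vertically down.
#   res_cm_per_m is the empirically calibrated resolution-altitude constant
#   (11.8 cm at 260 m AGL).
# hd_video: wide-angle HD action camera in the nose, 30 deg below horizontal.
# thermal: 640x480 microbolometer video, wing-mounted 15 deg off nadir
#   (75 deg depression); can be remounted at 30 deg below horizontal.
still_photo:
  dv_mm: 5.6
  dh_mm: 8.07
  f_mm: 5.1
  fps: 2.0
  mount_depression_deg: 90.0
  res_cm_per_m: 0.04538461538461539
hd_video:
  fov_diag_deg: 127.0
  px_h: 1920
  px_v: 1080
  fps: 30.0
  mount_depression_deg: 30.0
thermal:
  fov_diag_deg: 39.8
  px_h: 640
  px_v: 480
  fps: 25.0
  mount_depression_deg: 75.0
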