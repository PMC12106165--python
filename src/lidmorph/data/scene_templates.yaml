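# Generative templates for synthetic eye scenes.
#
# `base` holds the photographic-protocol defaults (primary gaze, 10 mm
# forehead fiducial); each condition overrides the geometric parameters that
# define it.  Two-element lists are uniform jitter ranges [low, high] sampled
# per scene; scalars are fixed.  Vertical geometry is specified relative to
# the horizontal canthus-to-canthus chord:
#   upper_peak_mm      lid-margin apex height above the chord
#   lower_dip_mm       lower-margin depth below the chord
#   cornea_height_mm   corneal-centre height above the chord
# so truth MRD1 = upper_peak - cornea_height and MRD2 = lower_dip + cornea_height.
base:
  image_size: [300, 440]          # (height, width) px
  chord_y_px: 180
  eye_offset_px: 30               # eye-centre offset from the image midline
  mm_per_px: 0.2
  icd_mm: [27.0, 30.0]
  upper_peak_mm: [4.0, 5.0]
  lower_dip_mm: [2.6, 3.4]
  cornea_height_mm: [0.5, 1.0]
  cornea_radius_mm: [5.3, 5.7]
  cornea_dx_mm: [-1.0, 1.0]       # horizontal corneal-centre jitter
  fold_type: none
  fold_extent_mm: [1.5, 2.5]
  entropion_flag: false
  trichiasis_flag: false
  ectropion_flag: false
  tumor_radius_mm: null
  marker_center_px: [48, 220]
  marker_diameter_mm: 10.0
  noise_sd: 3.0

conditions:
  normal: {}
  ptosis:
    upper_peak_mm: [1.8, 2.4]
    cornea_height_mm: [0.8, 1.2]      # truth MRD1 in [0.6, 1.6] mm
  upper_retraction:
    upper_peak_mm: [6.2, 7.0]
    cornea_height_mm: [0.5, 0.9]      # truth MRD1 in [5.3, 6.5] mm
  lower_retraction:
    lower_dip_mm: [5.4, 6.0]
    cornea_height_mm: [0.5, 0.9]      # truth MRD2 in [5.9, 6.9] mm
  ectropion:
    ectropion_flag: true
  entropion_trichiasis:
    entropion_flag: true
    trichiasis_flag: true
  tumor:
    tumor_radius_mm: [1.7, 2.3]
  epicanthus_inversus:
    fold_type: epicanthus_inversus
  epicanthus_other:
    fold_type: epicanthus_other
  bpes:
    icd_mm: [19.0, 22.0]
    upper_peak_mm: [1.8, 2.4]
    cornea_height_mm: [0.8, 1.2]
    fold_type: epicanthus_inversus
  blepharoptosis_trichiasis:
    upper_peak_mm: [1.8, 2.4]
    cornea_height_mm: [0.8, 1.2]
    entropion_flag: true
    trichiasis_flag: true
  blepharoptosis_epicanthus_other:
    upper_peak_mm: [1.8, 2.4]
    cornea_height_mm: [0.8, 1.2]
    fold_type: epicanthus_other
  blepharoptosis_ectropion:
    upper_peak_mm: [1.8, 2.4]
    cornea_height_mm: [0.8, 1.2]
    ectropion_flag: true

# Disease-level aliases resolve to the change-level template above.
aliases:
  blepharoptosis: ptosis
  tao: upper_retraction
  eyelid_tumor: tumor
  entropion_and_trichiasis: entropion_trichiasis
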