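# Calibrated landmark parameter set (working/right side coordinates, metres;
# origin at the incisal end point IS, x anterior, y left, z superior).
# The non-working side is the mirror image through the sagittal plane.
# Regenerate with scripts/calibrate_default.py.
intercondylar_width: 0.09391550409101035
condyle:
  x: -0.11499998604615523
  z: 0.02144019192212005
iw:
- -0.025000000000278425
- -0.020341870512198965
- -0.019999999999999997
masseter:
  origin:
  - -0.08147850741089138
  - -0.052
  - 0.11999999999999998
  insertion:
  - -0.09999996795522906
  - -0.05
  - 0.009999999999992343
medial_pterygoid:
  origin:
  - -0.08139393081535119
  - -0.028
  - 0.11999999999999998
  insertion:
  - -0.09804064590224795
  - -0.045
  - 0.00999999999999956
temporalis:
  origin:
  - -0.09495004795063577
  - -0.052
  - 0.05000000000005852
  insertion:
  - -0.045000000000000005
  - -0.048
  - 0.026135074101547594
v_weights:
  origin: 0.47017425444105304
  insertion: 0.47017425444105304
guide_plane:
  slope_deg: 3.5070840891059105
  medial_deg: -29.99999999996899
working_plane:
  slope_deg: 4.619833497259175
  medial_deg: -29.999999999723308
temporalis_parts:
  anterior_length: 0.075
  middle_length: 0.08
  posterior_length: 0.085
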