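# Synthetic stand-in for the experimental AP-biomarker calibration windows.
#
# The original calibration table for the human ventricular control population
# is not redistributable here; these windows are populated from the published
# human ventricular ranges of the population-of-models literature (undiseased
# human hearts, 1 Hz pacing) and are intentionally wide.  Units: APD*/tri in
# ms, dvdt_max in mV/ms (= V/s), v_peak and rmp in mV.
ranges:
  apd40:
    min: 85.0
    max: 320.0
  apd50:
    min: 110.0
    max: 350.0
  apd90:
    min: 180.0
    max: 440.0
  tri_90_40:
    min: 50.0
    max: 150.0
  dvdt_max:
    min: 100.0
    max: 1000.0
  v_peak:
    min: 10.0
    max: 55.0
  rmp:
    min: -95.0
    max: -80.0
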