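# Striatal D2 occupancy-versus-dose anchors per drug: [dose_mg, occupancy].
# Values are representative of the published PET displacement literature for
# each compound (order-of-magnitude anchors, config data rather than study
# output).  standard_dose_mg values are the standard clinical doses used for
# all standard-dose simulations.
aripiprazole:
  standard_dose_mg: 20
  anchors:
    - [10, 0.80]
    - [20, 0.87]
    - [30, 0.92]
clozapine:
  standard_dose_mg: 200
  anchors:
    - [100, 0.30]
    - [200, 0.45]
    - [400, 0.60]
haloperidol:
  standard_dose_mg: 10
  anchors:
    - [2, 0.60]
    - [5, 0.73]
    - [10, 0.82]
olanzapine:
  standard_dose_mg: 15
  anchors:
    - [5, 0.55]
    - [15, 0.75]
    - [30, 0.83]
paliperidone:
  standard_dose_mg: 9
  anchors:
    - [3, 0.45]
    - [6, 0.62]
    - [9, 0.72]
    - [12, 0.78]
quetiapine:
  standard_dose_mg: 400
  anchors:
    - [150, 0.20]
    - [400, 0.40]
    - [800, 0.55]
risperidone:
  standard_dose_mg: 4
  anchors:
    - [2, 0.55]
    - [4, 0.72]
    - [6, 0.79]
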