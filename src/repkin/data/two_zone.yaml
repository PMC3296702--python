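boundary:
  mode: periodic
initiation:
  background: 0.0
  zones:
  - amplitude: 1.0e-05
    center: 200.0
    shape: gaussian
    width: 25.0
  - amplitude: 0.0001
    center: 800.0
    shape: gaussian
    t_on: 5000.0
    width: 25.0
velocity:
  v_minus: 0.04
  v_plus: 0.04
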