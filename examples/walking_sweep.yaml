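# Walking-driven comparison of rigid pole lengths (gait-like synthetic input).
variant: NSNR
loads: {m1: 10.0, m2: 10.0}
contact: {kds: 500.0, khs: 10000.0}
control: {enabled: true, Kp: 1000.0, Kd: 500.0, Dh: 0.3}
scenario: walking
walking:
  duration: 12.0
  step_freq: 1.8
  Ax: 0.010
  Ay: 0.025
sweep:
  param: pole.L
  values: [1.4, 1.8]
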