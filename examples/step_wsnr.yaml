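# Controlled step response of the compliant pole (tip stiffness 500 N/m),
# compared against the published parameter set.
variant: WSNR
pole: {L: 1.4, k: 500.0}
loads: {m1: 10.0, m2: 10.0}
contact: {kds: 500.0, khs: 10000.0}
control: {enabled: true, Kp: 1000.0, Kd: 500.0, Dh: 0.3}
scenario: step
step:
  amplitude: null        # null -> calibrate to 15 deg at 1 s on the rigid pole
  duration: 20.0
  rise_time: 0.3
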