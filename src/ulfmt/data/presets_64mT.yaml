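# Tissue presets for 64 mT simulations.
#
# These are literature-informed estimates chosen once for this package, NOT
# measured values: two-pool parameters (bound_fraction, exchange_rate,
# t1_bound, t2_bound) of dairy cream, hair conditioner and brain tissue at
# ultra-low field are not tabulated anywhere authoritative. Free-pool T1
# values are shortened relative to clinical field strengths, T2 values kept
# similar, as is typical below 100 mT. Times in ms except t2_bound (us);
# exchange_rate in 1/s.
tissues:
  water:
    t1_free: 3000.0
    t2_free: 2000.0
    bound_fraction: 0.0
  csf_like:
    t1_free: 2000.0
    t2_free: 1500.0
    bound_fraction: 0.0
  wm_like:
    t1_free: 350.0
    t2_free: 90.0
    bound_fraction: 0.10
    exchange_rate: 25.0
    t1_bound: 300.0
    t2_bound: 10.0
    lineshape: gaussian
  cream_like:
    t1_free: 800.0
    t2_free: 70.0
    bound_fraction: 0.04
    exchange_rate: 30.0
    t1_bound: 300.0
    t2_bound: 10.0
    lineshape: gaussian
  conditioner_like:
    t1_free: 500.0
    t2_free: 150.0
    bound_fraction: 0.10
    exchange_rate: 35.0
    t1_bound: 300.0
    t2_bound: 10.0
    lineshape: gaussian

protocol:
  tr: 12.03
  flip_angle: 60.0
  pulse_width: 220.0
  sequence: psif_echo
  fov: [180.0, 220.0, 200.0]
  voxel: [2.0, 2.0, 5.0]
  bandwidth_khz: 18.0
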