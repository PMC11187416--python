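# Frozen default quantitation templates (published coefficients).
# slope: g/L per AU (empirical epsilon*l, inverted); intercept: g/L
# (constant absorbing media background). Do not edit: fitting produces new
# template files rather than mutating these.
glucose:
  slope: 870.29
  intercept: 6.955
  band:
    location_window: [1058.0, 978.0]
    baseline_window: [1058.0, 1004.0]
    nominal_center: 1035.0
glutamate:
  slope: 526.196
  intercept: 0.6888
  band:
    location_window: [1413.0, 1393.0]
    baseline_window: [1436.0, 1379.0]
    nominal_center: 1400.0
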