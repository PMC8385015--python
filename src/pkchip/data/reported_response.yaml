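# Published SW620 response readouts used as worked-example inputs.
# relative_volume_day7: spheroid volume on day 7 as percent of untreated control
# (perfused chip). percent_gi: percent growth inhibition vs control, in vitro at
# day 7 (chip) and in vivo at day 15 (xenograft).
relative_volume_day7:
  mono: 55
  combo_1_7: 22
  combo_7_7: 17
  combo_gap24: 25
  combo_gap72: 40
percent_gi:
  invitro_day7:
    mono: 52
    combo_gap24: 88
    combo_gap72: 70
  invivo_day15:
    mono: 53
    combo_gap24: 69
    combo_gap72: 46
static_reference:
  sn38_cmax_nM: 5.5
  azd0156_cmax_nM: 192
  exposure_days: 6
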