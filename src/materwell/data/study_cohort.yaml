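groups:
  ASD:
    n: 66
    child_age:
    - 15.5
    - 6.5
    maternal_age:
    - 47.9
    - 6.8
    p_male: 0.864
    p_max_selfhelp: 0.892
  AS:
    n: 28
    child_age:
    - 10.9
    - 3.3
    maternal_age:
    - 40.8
    - 4.9
    p_male: 0.464
    p_max_selfhelp: 0.143
  CdLS:
    n: 44
    child_age:
    - 12.8
    - 8.2
    maternal_age:
    - 45.1
    - 9.1
    p_male: 0.477
    p_max_selfhelp: 0.409
  DS:
    n: 29
    child_age:
    - 25.4
    - 11.8
    maternal_age:
    - 59.1
    - 12.3
    p_male: 0.533
    p_max_selfhelp: 0.9
  FXS:
    n: 102
    child_age:
    - 15.0
    - 8.2
    maternal_age:
    - 45.6
    - 9.5
    p_male: 1.0
    p_max_selfhelp: 0.882
  PMS:
    n: 31
    child_age:
    - 11.3
    - 8.4
    maternal_age:
    - 42.3
    - 9.9
    p_male: 0.452
    p_max_selfhelp: 0.226
  PWS:
    n: 101
    child_age:
    - 12.2
    - 8.1
    maternal_age:
    - 44.5
    - 8.5
    p_male: 0.523
    p_max_selfhelp: 0.782
  RTT:
    n: 87
    child_age:
    - 20.1
    - 10.2
    maternal_age:
    - 50.7
    - 9.2
    p_male: 0.0
    p_max_selfhelp: 0.05
  RTS:
    n: 47
    child_age:
    - 21.3
    - 10.5
    maternal_age:
    - 49.8
    - 9.9
    p_male: 0.553
    p_max_selfhelp: 0.809
  SMS:
    n: 20
    child_age:
    - 11.6
    - 7.2
    maternal_age:
    - 43.7
    - 8.5
    p_male: 0.6
    p_max_selfhelp: 0.6
  Soto:
    n: 38
    child_age:
    - 15.3
    - 9.3
    maternal_age:
    - 46.3
    - 8.3
    p_male: 0.684
    p_max_selfhelp: 0.842
  TSC:
    n: 71
    child_age:
    - 18.8
    - 10.7
    maternal_age:
    - 48.1
    - 10.3
    p_male: 0.606
    p_max_selfhelp: 0.662
  1p36:
    n: 26
    child_age:
    - 10.9
    - 8.9
    maternal_age:
    - 41.2
    - 10.8
    p_male: 0.786
    p_max_selfhelp: 0.423
  8p23:
    n: 22
    child_age:
    - 10.8
    - 5.5
    maternal_age:
    - 39.6
    - 6.1
    p_male: 0.682
    p_max_selfhelp: 0.591
measures:
  pgs:
    group_means:
      ASD: 21.66
      AS: 21.55
      CdLS: 21.66
      DS: 22.42
      FXS: 21.66
      PMS: 22.98
      PWS: 21.06
      RTT: 22.71
      RTS: 22.7
      SMS: 21.7
      Soto: 21.78
      TSC: 21.64
      1p36: 21.64
      8p23: 21.89
    child_age: 0.0
    maternal_age: 0.0
    wessex_max: 0.0
    person_sd: 3.2
    item_sd: 0.6
  pas5:
    group_means:
      ASD: 15.25
      AS: 16.6
      CdLS: 15.51
      DS: 15.93
      FXS: 15.77
      PMS: 16.03
      PWS: 15.65
      RTT: 17.23
      RTS: 15.07
      SMS: 15.62
      Soto: 15.53
      TSC: 15.32
      1p36: 15.63
      8p23: 16.86
    child_age: 0.0
    maternal_age: 0.0
    wessex_max: 0.0
    person_sd: 2.0
    item_sd: 0.6
  hads:
    group_means:
      ASD: 7.12
      AS: 6.03
      CdLS: 6.92
      DS: 4.79
      FXS: 5.61
      PMS: 6.13
      PWS: 6.12
      RTT: 4.7
      RTS: 5.36
      SMS: 7.66
      Soto: 5.42
      TSC: 5.88
      1p36: 6.96
      8p23: 4.82
    child_age: 0.0
    maternal_age: 0.0
    wessex_max: 0.0
    person_sd: 2.3
    item_sd: 0.5
  stress:
    group_means:
      ASD: 6.0
      AS: 5.0
      CdLS: 5.0
      DS: 3.0
      FXS: 4.0
      PMS: 5.0
      PWS: 4.0
      RTT: 4.0
      RTS: 5.0
      SMS: 6.0
      Soto: 4.0
      TSC: 5.0
      1p36: 5.0
      8p23: 4.0
    child_age: 0.0
    maternal_age: 0.0
    wessex_max: 0.0
    person_sd: 1.6
    item_sd: 0.3
missing_item_rate: 0.0
p_nonmother: 0.0
p_child_under2: 0.0
wessex_min: 3
wessex_max: 9
scq_mean: 22.0
scq_sd: 4.0
scq_floor: 15
seed: 0
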