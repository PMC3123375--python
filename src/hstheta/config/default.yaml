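# Canonical "control" parameter set for the hippocampo-septal theta network.
#
# Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2.  Calcium concentrations are in
# the arbitrary units of the source cell models.  Gate kinetics are listed
# once under `kinetics` and referenced by name from the channel tables.
# Values were tuned once so that the control network expresses a robust
# 4-7 Hz hippocampo-septal rhythm with sparsely firing pyramidal cells;
# they define the "healthy control" condition of the perturbation study.
cells:
  basket:
    cm: 1.0
    soma:
      channels:
        k:
          e_rev: -90.0
          g_max: 9.0
          gates:
          - exponent: 4
            gate: k_n
        leak:
          e_rev: -65.0
          g_max: 0.1
        na:
          e_rev: 55.0
          g_max: 35.0
          gates:
          - exponent: 3
            gate: na_m
          - exponent: 1
            gate: na_h
  msgaba:
    cm: 1.0
    soma:
      channels:
        k:
          e_rev: -90.0
          g_max: 9.0
          gates:
          - exponent: 4
            gate: k_n
        ks:
          e_rev: -90.0
          g_max: 15.0
          gates:
          - exponent: 1
            gate: ks_p
          - exponent: 1
            gate: ks_q
        leak:
          e_rev: -65.0
          g_max: 0.1
        na:
          e_rev: 55.0
          g_max: 35.0
          gates:
          - exponent: 3
            gate: na_m
          - exponent: 1
            gate: na_h
  olm:
    cm: 1.0
    pools:
      ahp:
        b: 1.0
        k_unit: 0.13
        tau_ca: 120.0
    soma:
      channels:
        ahp:
          ca_kd: 5.0
          ca_pool: ahp
          e_rev: -80.0
          g_max: 5.0
          gates: []
        ca:
          e_rev: 120.0
          g_max: 0.5
          gates:
          - exponent: 2
            gate: ca_m
        h:
          e_rev: -40.0
          g_max: 0.1
          gates:
          - exponent: 1
            gate: h_r
        k:
          e_rev: -80.0
          g_max: 11.0
          gates:
          - exponent: 4
            gate: k_n
        leak:
          e_rev: -65.0
          g_max: 0.1
        na:
          e_rev: 55.0
          g_max: 35.0
          gates:
          - exponent: 3
            gate: na_m
          - exponent: 1
            gate: na_h
  pyramidal:
    cm: 1.0
    dendrite:
      channels:
        a:
          e_rev: -80.0
          g_max: 10.0
          gates:
          - exponent: 1
            gate: a_a
          - exponent: 1
            gate: a_b
        ahp:
          ca_kd: 0.5
          ca_pool: ahp
          e_rev: -80.0
          g_max: 1.0
          gates: []
        ca:
          e_rev: 120.0
          g_max: 0.5
          gates:
          - exponent: 2
            gate: ca_m
        ct:
          ca_kd: 0.5
          ca_pool: ct
          e_rev: -80.0
          g_max: 2.0
          gates:
          - exponent: 1
            gate: bk_m
        h:
          e_rev: -40.0
          g_max: 0.1
          gates:
          - exponent: 1
            gate: h_r
        leak:
          e_rev: -65.0
          g_max: 0.1
    g_c: 2.0
    p_soma: 0.5
    pools:
      ahp:
        b: 1.0
        k_unit: 0.13
        tau_ca: 80.0
      ct:
        b: 1.0
        k_unit: 0.13
        tau_ca: 8.0
    soma:
      channels:
        a:
          e_rev: -80.0
          g_max: 4.0
          gates:
          - exponent: 1
            gate: a_a
          - exponent: 1
            gate: a_b
        ca:
          e_rev: 120.0
          g_max: 0.5
          gates:
          - exponent: 2
            gate: ca_m
        h:
          e_rev: -40.0
          g_max: 0.1
          gates:
          - exponent: 1
            gate: h_r
        k:
          e_rev: -80.0
          g_max: 15.0
          gates:
          - exponent: 4
            gate: k_n
        leak:
          e_rev: -65.0
          g_max: 0.1
        na:
          e_rev: 55.0
          g_max: 60.0
          gates:
          - exponent: 3
            gate: na_m
          - exponent: 1
            gate: na_h
kinetics:
  a_a:
    form: inf_tau
    k: 12.0
    tau0: 2.0
    vh: -45.0
  a_b:
    form: inf_tau
    k: -6.0
    tau0: 100.0
    vh: -72.0
  bk_m:
    form: inf_tau
    k: 6.0
    tau0: 1.0
    vh: -15.0
  ca_m:
    form: inf_tau
    k: 6.0
    tau0: 1.0
    vh: -10.0
  h_r:
    form: inf_tau
    k: -10.0
    tau0: 180.0
    vh: -80.0
  k_n:
    alpha:
      a: 0.01
      k: 10.0
      kind: linoid
      vh: -34.0
    beta:
      a: 0.125
      k: -80.0
      kind: exponential
      vh: -44.0
    form: alpha_beta
    phi: 5.0
  ks_p:
    form: inf_tau
    k: 3.0
    tau0: 120.0
    vh: -30.0
  ks_q:
    form: inf_tau
    k: -8.0
    tau0: 500.0
    vh: -55.0
  na_h:
    alpha:
      a: 0.07
      k: -20.0
      kind: exponential
      vh: -58.0
    beta:
      a: 1.0
      k: 10.0
      kind: sigmoid
      vh: -28.0
    form: alpha_beta
    phi: 5.0
  na_m:
    alpha:
      a: 0.1
      k: 10.0
      kind: linoid
      vh: -35.0
    beta:
      a: 4.0
      k: -18.0
      kind: exponential
      vh: -60.0
    form: alpha_beta
    phi: 20.0
populations:
  basket:
    mu_i: 1.2
    n: 100
    sigma_i: 0.1
  msgaba:
    mu_i: 1.0
    n: 50
    sigma_i: 0.1
  olm:
    mu_i: -0.5
    n: 30
    sigma_i: 0.1
  pyramidal:
    mu_i: 14.9
    n: 10
    sigma_i: 0.1
projections:
- compartment: soma
  g_max: 0.02
  in_degree: 5
  source: pyramidal
  target: basket
  transmitter: ampa
- compartment: soma
  g_max: 0.15
  in_degree: 10
  source: pyramidal
  target: olm
  transmitter: ampa
- compartment: soma
  g_max: 0.05
  in_degree: 10
  source: pyramidal
  target: olm
  transmitter: nmda
- compartment: soma
  g_max: 0.1
  in_degree: 30
  source: basket
  target: pyramidal
  tau_decay: 8.0
  transmitter: gaba_a
- compartment: dendrite
  g_max: 0.08
  in_degree: 10
  source: olm
  target: pyramidal
  tau_decay: 50.0
  transmitter: gaba_a
- compartment: soma
  g_max: 0.01
  in_degree: 10
  source: basket
  target: basket
  tau_decay: 5.0
  transmitter: gaba_a
- compartment: soma
  g_max: 0.05
  in_degree: 10
  source: msgaba
  target: basket
  tau_decay: 20.0
  transmitter: gaba_a
- compartment: soma
  g_max: 0.05
  in_degree: 10
  source: olm
  target: msgaba
  tau_decay: 20.0
  transmitter: gaba_a
- compartment: soma
  g_max: 0.01
  in_degree: 10
  source: msgaba
  target: msgaba
  transmitter: gaba_a
- compartment: soma
  g_max: 0.1
  in_degree: 10
  source: msgaba
  target: olm
  tau_decay: 20.0
  transmitter: gaba_a
simulation:
  dt_ms: 0.05
  duration_ms: 10000.0
  noise_sd_mv: 1.5
  noise_tau_ms: 1.0
  record_dt_ms: 1.0
  spike_min_separation_ms: 2.0
  spike_threshold_mv: 0.0
  transient_discard_ms: 1000.0
synapses:
  ampa:
    e_rev: 0.0
    tau_decay: 3.0
    tau_rise: 0.5
  gaba_a:
    e_rev: -75.0
    tau_decay: 8.0
    tau_rise: 0.5
  nmda:
    e_rev: 0.0
    tau_decay: 100.0
    tau_rise: 5.0
    voltage_dependence: true
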