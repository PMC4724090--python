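# Bundled radiobiological model-parameter sets, keyed by citation label.
# TCP: Poisson-LQ dose-response (D50 on the EQD2 scale, normalized gradient
# gamma, tumor alpha/beta). LKB: D50 / volume-effect exponent n / slope m,
# each paired with the alpha/beta used for its EQD2 correction. Seriality:
# relative-seriality Poisson model (D50, gamma, seriality s).
version: 1
tcp:
  willner_24mo:
    d50_eqd2_gy: 74.5
    gamma: 3.5
    alpha_beta_gy: 10.0
    label: "Willner et al., 24-month local control"
  martel_24mo:
    d50_eqd2_gy: 72.0
    gamma: 2.0
    alpha_beta_gy: 10.0
    label: "Martel et al., 24-month local control"
  martel_30mo:
    d50_eqd2_gy: 84.5
    gamma: 1.5
    alpha_beta_gy: 10.0
    label: "Martel et al., 30-month local control"
lkb:
  lung_lkb.kwa:
    structure: lung
    d50_gy: 30.5
    n_volume: 1.0
    m_slope: 0.3
    alpha_beta_gy: 1.3
    endpoint: "lung pneumonitis grade >= 2 (Kwa et al.)"
  lung_lkb.seppenwoolde_ab1.3:
    structure: lung
    d50_gy: 30.8
    n_volume: 0.99
    m_slope: 0.37
    alpha_beta_gy: 1.3
    endpoint: "lung pneumonitis grade >= 2 (Seppenwoolde et al., alpha/beta 1.3)"
  lung_lkb.seppenwoolde_ab3:
    structure: lung
    d50_gy: 30.8
    n_volume: 0.99
    m_slope: 0.37
    alpha_beta_gy: 3.0
    endpoint: "lung pneumonitis grade >= 2 (Seppenwoolde et al., alpha/beta 3)"
  lung_lkb.burman:
    structure: lung
    d50_gy: 24.5
    n_volume: 0.87
    m_slope: 0.18
    alpha_beta_gy: 1.3
    endpoint: "lung pneumonitis grade >= 2 (Burman et al.)"
  esophagus_lkb.esophagitis:
    structure: esophagus
    d50_gy: 51.0
    n_volume: 0.44
    m_slope: 0.32
    alpha_beta_gy: 10.0
    endpoint: "esophagitis grade >= 2"
  heart_lkb.pericarditis:
    structure: heart
    d50_gy: 60.6
    n_volume: 0.64
    m_slope: 0.13
    alpha_beta_gy: 2.5
    endpoint: "pericarditis"
seriality:
  cord_plq.myelitis:
    structure: cord
    d50_gy: 68.6
    gamma: 1.9
    s_seriality: 4.0
    alpha_beta_gy: 3.0
    endpoint: "spinal cord myelitis/necrosis"
  esophagus_plq.stricture:
    structure: esophagus
    d50_gy: 68.6
    gamma: 2.8
    s_seriality: 3.4
    alpha_beta_gy: 3.0
    endpoint: "esophagus clinical stricture"
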