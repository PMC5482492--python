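# Default parameter set: kinetic constants, conductances and
# conserved-pool totals of the two-compartment energy-redox +
# beta-oxidation model.  Units: concentrations mM, time s,
# potentials mV, conductances mM s-1 mV-1, Vmax mM s-1.
compartment:
  mito_volume_per_mg_protein: 1.0
  volume_ratio_extra_to_matrix: 10.0
  membrane_capacitance: 0.001812
  z_temp_mV: 61.5
proton_circuit:
  g_H0: 0.018
  k_PCoA: 11500.0
  pcoa_uncoupling_exponent: 4
respiratory_chain:
  Vmax_C1: 12.0
  Km_C1_nadh: 0.1
  pmf0_C1: 220.0
  kpmf_C1: 12.0
  Vmax_SDH: 1.5
  Km_SDH_suc: 0.5
  pmf0_SDH: 220.0
  kpmf_SDH: 12.0
  Vmax_ETFQO: 4.0
  Km_ETFQO_etfh2: 0.004
  pmf0_ETFQO: 220.0
  kpmf_ETFQO: 12.0
ros_generation:
  shunt_frac: 0.015
  dpsi_ros_half: 185.0
  k_ros_dpsi: 12.0
  ros_matrix_fraction: 0.8
phosphorylation:
  Vmax_F1F0: 8.0
  Km_F1_adp: 0.01
  Km_F1_pi: 1.0
  pmf0_F1: 160.0
  kpmf_F1: 10.0
  Vmax_ANT: 10.0
  Km_ANT_adp_e: 0.012
  Km_ANT_atp_m: 0.5
  k_PiT: 5.0
  Vmax_NNT: 0.05
  Km_NNT_nadh: 0.1
  Km_NNT_nadp: 0.02
tca_cycle:
  Vmax_CS: 10.0
  Km_CS_accoa: 0.01
  Km_CS_oaa: 0.0005
  Vmax_IDH: 2.0
  Km_IDH_cit: 0.5
  Km_IDH_nad: 0.1
  Vmax_IDH_nadp: 0.05
  Km_IDH_nadp: 0.02
  Vmax_KGDH: 2.0
  Km_KGDH_akg: 0.5
  Km_KGDH_nad: 0.1
  Ki_KGDH_suc: 1.0
  Vmax_MDH: 8.0
  Km_MDH_mal: 0.5
  Km_MDH_nad: 0.1
  Keq_MDH: 0.0001
  Vmax_ME: 1.0
  Km_ME_mal: 0.5
  Km_ME_nad: 0.05
  Vmax_PDH: 1.0
  Km_PDH_pyr: 0.05
  Km_PDH_coash: 0.05
  Km_PDH_nad: 0.1
  Vmax_GDH: 1.0
  Km_GDH_glu: 2.0
  Km_GDH_nad: 0.1
  k_malT: 0.5
  Keq_malT: 10.0
  k_cit_export: 0.02
  k_akg_export: 0.01
  k_pyr_export: 0.01
beta_oxidation:
  Vmax_cpt1: 0.22
  Ki_cpt1_pcarn: 0.005
  Km_cpt1_pcoa: 0.015
  Km_cpt1_car: 0.125
  k_cact: 100.0
  Vmax_cpt2: 1.0
  Km_cpt2_acylcarnitine: 0.05
  Km_cpt2_coash: 0.15
  Vmax_vlcad: 0.3
  Km_vlcad_acyl: 0.005
  Vmax_lcad: 0.3
  Km_lcad_acyl: 0.005
  Vmax_mcad: 0.5
  Km_mcad_acyl: 0.005
  Vmax_scad: 0.5
  Km_scad_acyl: 0.005
  Km_acd_etf: 0.005
  Vmax_hydratase: 5.0
  Km_hydratase_enoyl: 0.02
  Vmax_hadh: 2.0
  Km_hadh_hydroxyacyl: 0.01
  Km_hadh_nad: 0.1
  Vmax_thiolase: 2.0
  Km_thiolase_ketoacyl: 0.005
  Km_thiolase_coash: 0.02
ros_scavenging:
  k_SOD_m: 1000.0
  k_SOD_e: 1000.0
  Vmax_GPx_m: 1.0
  Vmax_GPx_e: 0.05
  Km_GPx_h2o2: 0.01
  Km_GPx_gsh: 0.5
  Vmax_GR_m: 0.015
  Vmax_GR_e: 0.02
  Km_GR_gssg: 0.06
  Km_GR_nadph: 0.015
  Vmax_Prx_m: 0.05
  Vmax_Prx_e: 0.02
  Km_Prx_h2o2: 0.005
  Km_Prx_trx: 0.005
  Vmax_TrxR_m: 0.01
  Vmax_TrxR_e: 0.01
  Km_TrxR_trxss: 0.005
  Km_TrxR_nadph: 0.015
  k_CAT: 5.0
  NADPH_e_fixed: 0.05
  k_IMAC_o2neg: 50.0
  k_H2O2_diff: 20.0
  k_GSH_transport: 0.0001
  k_H2O2_out: 5.0
activity_scaling:
  GR_scale: 1.0
  TrxR_scale: 1.0
pools:
  NAD_tot: 1.0
  NADP_tot: 0.1
  GSH_tot_m: 1.0
  GSH_tot_e: 1.0
  Trx_tot_m: 0.02
  Trx_tot_e: 0.01
  CoA_tot: 1.0
  carnitine_tot: 6.00011
  ETF_tot: 0.02
  adenine_tot_m: 10.0
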