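begin molecule types
  INS()
  IR(loc~mem~cyt,ins~0~1~2,Y~0~P)
  IRS1(Y~0~P,S~0~P,pi3k,gs,shp2)
  PI3K(irs)
  GS(irs,cat~on~off)
  SHP2(irs)
  LIPID(s~pip2~pip3)
  AKT(T~0~P,S~0~P)
  PKC(T~0~P)
  GLUT4(loc~cyt~mem)
  AMPK(T~0~P)
  TSC(S~0~P,Y~0~P)
  AA()
  MTORC1(S~0~P)
  P70(T~0~P)
  PI3KV(s~i~a)
  MTORC2(s~i~a)
  SRC(s~i~a)
  RAS(s~GDP~GTP)
  RAF(s~i~a)
  MEK(S~0~P)
  ERK(T~0~P,Y~0~P)
end molecule types
begin parameters
  k1 3.321e-05
  k_1 0.4
  k2 3.321e-05
  k_2 4.0
  k_3 0.2
  k4p 0.05
  k6 1.0
  k_4 0.5
  k7 3.5e-05
  k_7 1.5
  Kd_akt 50000.0
  n_akt 1.5
  k7p 0.02
  k_7p 0.3
  Vmax 0.35
  Kd_pkc 40000.0
  n 2.0
  k15 4.0
  Kd_p70 9000.0
  n_p70 4.0
  k8 1e-05
  k_8 0.5
  k40 2e-05
  k_40 0.1
  k42 2e-05
  k_42 0.1
  k41 2.0
  k9a 6e-06
  k9s 4.0
  k11 4.0
  Kd_pip3 5000.0
  k_11 1.0
  k19 3.0
  Kd_mt2 9000.0
  k_19 1.0
  k12 2.0
  k_12 0.5
  k13 0.0020833
  k_13 0.05
  k13p 0.08
  Kd_g4 60000.0
  n_akt4 2.0
  k13p2 0.02
  k14 96.0
  k_14 0.001
  k16 0.5
  k_16 1.5
  Kd_irs 30000.0
  n_irs 2.0
  k21 1.0
  Kd_ampk 5000.0
  n_ampk 2.0
  k22 0.5
  k_21 0.18
  Kd_aktT 40000.0
  n_aktT 1.0
  k_22 0.1
  k17 0.3
  Kd_aa 50000.0
  n_aa 1.0
  k18 2.0
  Kd_tsc 4000.0
  n_tsc 2.0
  k20 0.3
  Kd_mt1 25000.0
  k_20 0.2
  k23 2.0
  Kd_irm 40000.0
  k_23 0.5
  k24 2.0
  Kd_p3v 5000.0
  k_24 0.5
  kcat24 0.3
  Kd_src 80000.0
  n_src 1.0
  kcat25 0.5
  alpha24 1e-05
  kcat27 1.0
  kcat28 0.8
  Kd_gs 6000.0
  n_gs 2.0
  kcat29 0.3
  kcat30 3.0
  Kd_ras 8000.0
  n_ras 2.0
  kcat31 1e-06
  kcat32 4e-05
  kcat33 1.0
  Kd_raf 4000.0
  n_raf 2.0
  kcat34 0.8
  kcat35 1.5
  Kd_mek 25000.0
  n_mek 2.0
  kcat36 1.5
  kcat37 0.6
  kcat38 0.6
  kcat39 0.8
  Kd_erk 30000.0
  n_erk 2.0
  k_39 0.05
end parameters
begin seed species
  $INS() 0.0
  $AA() 100000.0
  IR(Y~0,ins~0,loc~mem) 100000.0
  IRS1(S~0,Y~0,gs,pi3k,shp2) 58297.0
  IRS1(S~P,Y~0,gs,pi3k,shp2) 41703.0
  PI3K(irs) 100000.0
  GS(cat~on,irs) 10000.0
  SHP2(irs) 10000.0
  LIPID(s~pip2) 100000.0
  AKT(S~0,T~0) 100000.0
  PKC(T~0) 100000.0
  GLUT4(loc~cyt) 96000.0
  GLUT4(loc~mem) 4000.0
  AMPK(T~P) 10000.0
  TSC(S~P,Y~0) 10000.0
  MTORC1(S~0) 26881.71
  MTORC1(S~P) 3118.29
  P70(T~0) 34294.920000000006
  P70(T~P) 5705.080000000001
  PI3KV(s~i) 10000.0
  MTORC2(s~i) 18800.0
  SRC(s~i) 10000.0
  RAS(s~GDP) 20000.0
  RAF(s~i) 10000.0
  MEK(S~0) 50000.0
  ERK(T~0,Y~0) 50000.0
end seed species
begin observables
  IR_phos IR(Y~P)
  IR_phos_mem IR(Y~P,loc~mem)
  IRS1_pY IRS1(Y~P)
  pIRS1_Ser IRS1(S~P)
  IRS1_PI3K IRS1(pi3k!1).PI3K(irs!1)
  PIP3 LIPID(s~pip3)
  pAKT_T309 AKT(T~P)
  pAKT_S473 AKT(S~P)
  AKT_act AKT(T~P) AKT(S~P,T~0)
  PKC_act PKC(T~P)
  GLUT4_drivers_akt AKT(T~P) AKT(S~P,T~0)
  GLUT4_mem GLUT4(loc~mem)
  GLUT4_cyt GLUT4(loc~cyt)
  AMPK_act AMPK(T~P)
  TSC_act TSC(S~P,Y~0)
  AA_level AA()
  pmTOR_S2448 MTORC1(S~P)
  pP70S6K_T389 P70(T~P)
  PI3Kv_act PI3KV(s~a)
  mTORC2_act MTORC2(s~a)
  GS_IRS1 IRS1(gs!1).GS(irs!1)
  GS_IRS1_active IRS1(gs!1).GS(cat~on,irs!1)
  SHP2_IRS1 IRS1(shp2!1).SHP2(irs!1)
  RAS_GTP RAS(s~GTP)
  RAF_act RAF(s~a)
  MEK_P MEK(S~P)
  ppERK ERK(T~P,Y~P)
end observables
begin reaction rules
  ins_binding_1: IR(Y~0,ins~0,loc~mem) + INS() <-> IR(Y~P,ins~1,loc~mem) ma(k1), ma(k_1)
  ins_binding_2: IR(Y~P,ins~1,loc~mem) + INS() <-> IR(Y~P,ins~2,loc~mem) ma(k2), ma(k_2)
  ir_surface_dephos: IR(Y~P,loc~mem) -> IR(Y~0,ins~0,loc~mem) ma(k_3)
  ir_internalization: IR(Y~P,loc~mem) -> IR(Y~P,ins~0,loc~cyt) ma(k4p)
  ir_internal_dephos: IR(Y~P,loc~cyt) -> IR(Y~0,loc~cyt) ma(k6)
  ir_externalization: IR(Y~0,ins~0,loc~cyt) -> IR(Y~0,ins~0,loc~mem) ma(k_4)
  irs1_tyr_phos: IR(Y~P) + IRS1(S~0,Y~0) -> IR(Y~P) + IRS1(S~0,Y~P) ma(k7)
  irs1_tyr_dephos: IRS1(Y~P,gs,pi3k,shp2) -> IRS1(Y~0,gs,pi3k,shp2) ihill(k_7; AKT_act; Kd_akt; n_akt)
  irs1_ser_basal: IRS1(S~0) <-> IRS1(S~P) ma(k7p), ma(k_7p)
  irs1_ser_phos_by_pkc: IRS1(S~0) -> IRS1(S~P) hill(Vmax; PKC_act; Kd_pkc; n)
  irs1_ser_phos_by_p70: IRS1(S~0) -> IRS1(S~P) hill(Vmax*k15; pP70S6K_T389; Kd_p70; n_p70)
  pi3k_binding: IRS1(S~0,Y~P,pi3k,shp2) + PI3K(irs) <-> IRS1(Y~P,pi3k!1,shp2).PI3K(irs!1) ma(k8), ma(k_8)
  gs_binding: IRS1(S~0,Y~P,gs,shp2) + GS(irs) <-> IRS1(Y~P,gs!1,shp2).GS(irs!1) ma(k40), ma(k_40)
  shp2_binding: IRS1(S~0,Y~P,gs,pi3k,shp2) + SHP2(irs) <-> IRS1(Y~P,gs,pi3k,shp2!1).SHP2(irs!1) ma(k42), ma(k_42)
  gs_release_on_ser: IRS1(S~P,gs!1).GS(irs!1) -> IRS1(S~P,gs) + GS(irs) ma(k41)
  shp2_release_on_ser: IRS1(S~P,shp2!1).SHP2(irs!1) -> IRS1(S~P,shp2) + SHP2(irs) ma(k41)
  pip3_synthesis: IRS1(S~0,pi3k!1).PI3K(irs!1) + LIPID(s~pip2) -> IRS1(S~0,pi3k!1).PI3K(irs!1) + LIPID(s~pip3) ma(k9a)
  pip3_degradation: LIPID(s~pip3) -> LIPID(s~pip2) ihill(k9s; AKT_act; Kd_akt; n_akt)
  akt_thr_phos: AKT(T~0) <-> AKT(T~P) hill(k11; PIP3; Kd_pip3; 1.0), ma(k_11)
  akt_ser_phos: AKT(S~0) <-> AKT(S~P) hill(k19; mTORC2_act; Kd_mt2; 1.0), ma(k_19)
  pkc_activation: PKC(T~0) <-> PKC(T~P) hill(k12; PIP3; Kd_pip3; 1.0), ma(k_12)
  glut4_basal_translocation: GLUT4(loc~cyt) <-> GLUT4(loc~mem) ma(k13), ma(k_13)
  glut4_stim_by_akt: GLUT4(loc~cyt) -> GLUT4(loc~mem) hill(k13p; GLUT4_drivers_akt; Kd_g4; n_akt4)
  glut4_stim_by_pkc: GLUT4(loc~cyt) -> GLUT4(loc~mem) hill(k13p2; PKC_act; Kd_g4; n_akt4)
  glut4_turnover: 0 <-> GLUT4(loc~cyt) ma(k14), ma(k_14)
  ampk_activation: AMPK(T~0) <-> AMPK(T~P) ma(k16), hill(k_16; IRS1_pY; Kd_irs; n_irs)
  tsc_ser_phos: TSC(S~0,Y~0) <-> TSC(S~P,Y~0) hill(k21; AMPK_act; Kd_ampk; n_ampk), hill(k22; pAKT_T309; Kd_aktT; n_aktT)
  tsc_tyr_phos: TSC(S~0,Y~0) <-> TSC(S~0,Y~P) hill(k_21; pAKT_T309; Kd_aktT; n_aktT), ma(k_22)
  mtorc1_activation: MTORC1(S~0) <-> MTORC1(S~P) hill(k17; AA_level; Kd_aa; n_aa), hill(k18; TSC_act; Kd_tsc; n_tsc)
  p70_activation: P70(T~0) <-> P70(T~P) hill(k20; pmTOR_S2448; Kd_mt1; 1.0), ma(k_20)
  pi3kv_activation: PI3KV(s~i) <-> PI3KV(s~a) hill(k23; IR_phos_mem; Kd_irm; 1.0), ma(k_23)
  mtorc2_activation: MTORC2(s~i) <-> MTORC2(s~a) hill(k24; PI3Kv_act; Kd_p3v; 1.0), ma(k_24)
  src_activation: SRC(s~i) <-> SRC(s~a) hill(kcat24; IR_phos; Kd_src; n_src), ma(kcat25)
  src_activation_via_shp2: IRS1(shp2!1).SHP2(irs!1) + SRC(s~i) -> IRS1(shp2!1).SHP2(irs!1) + SRC(s~a) ma(alpha24)
  ras_activation: RAS(s~GDP) <-> RAS(s~GTP) hill(kcat28; GS_IRS1_active; Kd_gs; n_gs), ma(kcat27)
  raf_activation: RAF(s~i) <-> RAF(s~a) hill(kcat30; RAS_GTP; Kd_ras; n_ras), ma(kcat29)
  raf_full_activation_by_src: SRC(s~a) + RAF(s~i) -> SRC(s~a) + RAF(s~a) ma(kcat31)
  raf_inactivation_by_akt: AKT(S~P) + RAF(s~a) -> AKT(S~P) + RAF(s~i) ma(kcat32)
  mek_phosphorylation: MEK(S~0) <-> MEK(S~P) hill(kcat33; RAF_act; Kd_raf; n_raf), ma(kcat34)
  erk_phos_thr: ERK(T~0,Y~0) <-> ERK(T~P,Y~0) hill(kcat35; MEK_P; Kd_mek; n_mek), ma(kcat38)
  erk_phos_tyr: ERK(T~P,Y~0) <-> ERK(T~P,Y~P) hill(kcat36; MEK_P; Kd_mek; n_mek), ma(kcat37)
  gs_inhibition_by_erk: GS(cat~on) <-> GS(cat~off) hill(kcat39; ppERK; Kd_erk; n_erk), ma(k_39)
end reaction rules
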