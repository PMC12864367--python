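# Synthetic default parameter set (day / cm^3 / cell / g / molec / mg units).
#
# This is NOT a transcription of a measured calibration: it is a synthetic,
# biologically plausible stand-in constructed so that
#   * the PD-1/PD-L1 dissociation rate lambda_Q equals 1.44 s^-1
#     (= 124416 day^-1), giving a complex mean lifetime below one second;
#   * the association/dissociation ratio lambda_PDPL / lambda_Q equals
#     2.13e-16 cm^3/molec, the value implied jointly by the baseline unbound
#     PD-1, PD-L1 and complex concentrations in both compartments;
#   * cytokine and checkpoint synthesis/decay balances reproduce the baseline
#     concentrations given the baseline cell densities;
#   * fast species (cytokines, effector pools in the TDLN, naive macrophages,
#     drug-bound complexes) relax at least an order of magnitude faster than
#     the slow cell populations, as the QSSA reduction assumes;
#   * without treatment the tumour persists near carrying capacity, while
#     triweekly 200 mg anti-PD-1 dosing drives a deep response.
#
# growth
lambda_C: 0.25
C_0: 5.0e7
# cancer elimination
lambda_CT8: 3.0e-8
lambda_CK: 9.0e-8
lambda_CIa: 0.1
K_CIb: 3.0e-7
K_CQT8: 5.0e5
K_CQK: 2.0e5
K_CIa: 2.0e-10
d_Nc: 0.2
# dendritic cells
A_D0: 3.5e5
lambda_DNc: 0.2
K_DNc: 2.0e6
lambda_D0K: 1.0e-8
K_D0Ib: 3.0e-7
lambda_DDLN: 0.095
d_D0: 0.1
d_D: 0.1
tau_m: 0.5
# CD8+ T-cell lineage
A_T08: 1.7e5
lambda_T08TA8: 2.4e-9
K_T08TAr: 4.0e5
K_TA8TAr: 4.0e5
K_T08Q8LN: 3.0e5
K_TA8Q8LN: 3.0e5
n8_max: 9
Delta8_0: 1.0
Delta8: 0.25
d_T08: 0.01
lambda_TA8T8: 3.0
tau_a: 0.2
lambda_T8I2: 0.07
K_T8I2: 2.0e-12
K_T8Tr: 4.0e5
lambda_T8C: 0.8
K_T8C: 1.0e7
lambda_TexA1: 1.0
K_TexA1: 1.0e13
d_T8: 0.15
d_Tex: 0.3
K_T8I10: 6.0e-11
K_TexI10: 6.0e-11
# Treg lineage
A_T0r: 1.35e4
lambda_T0rTAr: 1.2e-8
nr_max: 6
Deltar_0: 1.0
Deltar: 0.3
d_T0r: 0.01
lambda_TArTr: 2.0
d_Tr: 0.1
# macrophages
A_M0: 2.44e6
lambda_M1Ig: 1.0
K_M1Ig: 2.0e-11
lambda_M1Ia: 1.0
K_M1Ia: 5.0e-11
lambda_M2Ib: 1.4
K_M2Ib: 1.0e-7
lambda_M2I10: 0.2
K_M2I10: 6.0e-11
d_M0: 2.0
d_M2: 0.62
# NK cells
A_K0: 1.24e5
lambda_KI2: 1.0
K_KI2: 3.0e-12
lambda_KI12: 1.0
K_KI12: 2.0e-12
K_KIb: 3.0e-7
d_K0: 0.2
d_K: 0.02
# cytokines
lambda_I2T8: 8.99e-16
lambda_IgK: 1.06e-16
lambda_IaT8: 1.2e-14
lambda_IaK: 1.1e-15
lambda_IbC: 8.0e-13
lambda_IbM2: 4.7e-11
lambda_I10C: 1.74e-16
lambda_I12D: 5.02e-17
d_I2: 80.0
d_Ig: 30.0
d_Ia: 150.0
d_Ib: 80.0
d_I10: 50.0
d_I12: 40.0
# checkpoints and drug
lambda_PDT8: 2757.0
lambda_PDK: 552.0
lambda_PD8LN: 1200.0
lambda_PDA1: 1.4e-13
lambda_PDPL: 2.65e-11
lambda_QA: 8.6
lambda_Q: 124416.0
d_QA: 10.0
d_PD: 1.0
d_PL: 1.0
d_A1: 0.03
lambda_PLC: 1.5e5
lambda_PLM2: 7.0e5
lambda_PLLNDLN: 1.77e4
f_pembro: 1.5e12
# compartment volumes
V_TS: 14.0
V_LN: 1.0
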