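# Default kernel parameters for the reduced-form C/N ecosystem simulator.
# Units are documented on the Parameters dataclass.  Tuned once so that
# spin-up stocks land near boreal stand-level values (~2.2 kg C m-2
# vegetation, ~10.1 kg C m-2 soil) and the post-fire chronosequence keeps
# the expected sign structure across burn-severity classes.
version: 1
npp_max: 230.0
t_opt: 14.0
t_width: 13.0
w_half_npp: 30.0
n_half: 10.0
co2_beta: 0.4
k_litter: 0.0095
k_decomp: 0.018
q10: 2.0
t_ref: 10.0
cn_soil: 30.0
cn_veg: 50.0
imm_frac: 0.4
n_input: 0.0008
n_vol_frac: 0.7
insulation: 0.09
t_damp: 0.8
fol_linear_years: 5.0
fol_recovery_at_5: 0.25
fol_sig_steepness: 0.35
fol_sig_midpoint: 10.0
moss_tau: 40.0
moss_max: 15.0
et_coeff: 6.0
et_base: 0.97
bucket_mm: 400.0
w_half_rh: 300.0
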