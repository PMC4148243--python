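# Default DEB parameter set for Pisaster ochraceus.
# Units: J, cm, g, d, K. See the package methods note for provenance and
# for the choice of E_H_p.
X_K: 13.9
p_Am: 43.2
v: 0.04
kappa: 0.58
p_M: 40.43
p_M_starv: 11.5
E_G: 2743.0
E_H_b: 0.012
E_H_j: 100.0
E_H_p: 139000.0
delta_larv: 0.959
delta_post: 0.52
k_J: 2.9e-06
T_A: 6000.0
T_L: 280.0
T_H: 297.0
T_AL: 31000.0
T_AH: 190000.0
T_ref: 293.0
d_V: 1.0
w_E: 4.35e-05
W_E_mol: 23.9
mu_E: 550000.0
spawn_period: 365.0
# published standard deviations of the estimated parameters
X_K__sd: 2.3
p_Am__sd: 4.1
v__sd: 0.01
kappa__sd: 0.07
p_M__sd: 1.41
p_M_starv__sd: 2.74
E_G__sd: 97.22
E_H_b__sd: 4.8e-04
E_H_j__sd: 4.21
E_H_p__sd: 9.9e+07
delta_larv__sd: 144.56
delta_post__sd: 0.03
k_J__sd: 0.018
T_A__sd: 335.0
truncation_policy: truncnorm
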