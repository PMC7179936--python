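# Calibrated kinetic/yield constants of the producer (wild-type-derived) strain
# and the engineered acetate-cleaner strain.
# Units: rates g gDW^-1 h^-1; concentrations g L^-1; yields gDW g^-1; k_deg h^-1.
k_g = 1.53
K_g = 0.09
Theta_a = 0.52
n = 1.0
k_over = 0.17
l = 0.7
k_a = 0.97
K_a = 0.5
Theta_g = 0.25
m = 1.0
Y_g = 0.44
Y_a = 0.298
Y_h = 0.2
k_deg = 0.0044
k_dPTS = 0.38
k_Acs = 1.46
K_Acs = 0.012
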