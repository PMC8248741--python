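f_c: 0.01
f_er: 0.025
gamma: 9.0
j_inleak: 0.15
v_pmca: 30.0
k_pmca: 0.45
v_serca: 22.5
k_serca: 0.105
v_erleak: 0.03
d1: 0.13
d2: 1.049
d3: 0.9434
d5: 0.08234
a2: 0.2
v_ip3r: 15.0
g_x7: 2.5e-08
e_rev: 0.0
v_mem: -0.06
k1: 0.3
k2: 1265.0
k3: 2.4
k4: 1581.0
k5: 1.58
k6: 221.0
k7: 316.0
l1: 0.0001
l2: 0.004
l3: 0.3
h1: 0.001
h2_c2: 0.01
h2_q1: 0.05
h2_q2: 0.8
f_ca: 0.046
v_osteo: 6.5e-12
alpha_atp: 0.03
k_atp: 1.0
delta: 0.01
g_x7_units: siemens
binding_multiplicities: false
desensitized_ladder: true
restore_sensitized_affinity: true
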