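# experimental vs periodic-DFT (PBE-D3) lattice parameters, alpha-cisplatin polymorph
label,ref,calc
a_angstrom,6.2424,6.2218
b_angstrom,6.5087,6.4154
c_angstrom,6.7451,6.7697
alpha_deg,69.896,69.4619
beta_deg,83.710,82.9332
gamma_deg,87.348,87.3968
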