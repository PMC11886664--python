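# experimental vs periodic-DFT (PBE-D3) lattice parameters, beta-cisplatin polymorph
label,ref,calc
a_angstrom,6.2846,6.2901
b_angstrom,13.4990,13.3577
c_angstrom,6.6839,6.7008
alpha_deg,69.444,69.918
beta_deg,85.586,83.917
gamma_deg,82.229,80.913
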