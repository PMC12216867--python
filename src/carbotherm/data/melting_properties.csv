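name,t_m_K,dcp_J_mol_K,dh_m_J_mol
D-Glucose,423.2,183.0,42432
Xylose,416.2,97.3,29939
Xylitol,367.5,77.7,33678
D-galactose,438.1,153.0,43740
D-fructose,378.2,99.2,26029
Sucrose,459.1,261.0,46187
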