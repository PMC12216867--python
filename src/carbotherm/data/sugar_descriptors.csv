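name,t_c_K,v_c_cm3_mol,t_m_K
Glucose,1034.02,460,423.20
Xylose,900.63,391,416.20
Arabinose,890.40,343,433.00
Xylitol,947.50,393,367.50
Ribose,900.63,391,359.00
Galactose,1034.00,460,438.15
Fructose,1017.85,415,378.20
Mannose,1034.00,460,406.15
Sucrose,1782.70,784,459.15
Sorbitol,1092.90,462,373.80
Maltose,1783.80,777,377.20
Mannitol,1092.90,462,439.15
Lactose,1783.80,777,498.03
Trehalose,1783.80,777,368.15
Maltitol,1658.00,601,423.00
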