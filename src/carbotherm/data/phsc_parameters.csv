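name,r,sigma_A,eps_over_k_K,eps_assoc_over_k_K,kappa_assoc,n_sites,molar_mass_g_mol,t_K,max_molality,n_points,t_cell_verbatim
D-Glucose,7.919,3.240,338.532,2233.411,0.0701,10,180.156,303.0,4.8,24,303.084.8
Xylose,6.851,3.551,389.686,2268.548,0.055,8,150.130,308.15,3.0,20,308.153.020
L-Arabinose,8.078,2.121,194.955,2993.764,0.012,10,150.130,308.15,3.3,18,308.153.318
Xylitol,6.096,3.342,373.589,1526.725,0.032,10,152.146,308.15,3.3,19,308.153.319
D-Ribose,6.208,3.806,415.485,1572.824,0.057,10,150.130,308.15,3.3,20,308.153.320
D-galactose,7.911,2.969,418.363,2633.597,0.093,10,180.156,308.15,2.6,18,308.152.618
D-fructose,7.836,3.245,330.953,1495.777,0.068,10,180.156,308.15,5.5,21,308.155.521
D-mannose,9.175,2.445,336.939,2416.650,0.097,10,180.156,308.15,0.6,21,308.150.6212
Sucrose,9.269,3.396,376.442,1414.893,0.017,16,342.297,303.15,3.9,22,303.153.922
Sorbitol,6.039,3.514,401.366,1522.868,0.073,12,182.172,308.15,3.6,21,308.153.621
Raffinose,9.939,3.735,433.741,1324.792,0.012,20,504.437,308.15,0.6,28,308.150.628
Maltitol,6.245,4.000,457.875,1055.046,0.058,12,344.312,308.15,3.6,14,308.153.614
Maltose,5.382,3.977,471.902,1782.704,0.046,16,342.297,308.15,3.6,16,308.153.616
Water,1.405,3.043,460.520,1633.280,0.0380,2,18.015,278-640,,50,278-640
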