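# Tissue composition table for the tissue-composition (Rodgers-Rowland
# type) partition method: fractional extracellular/intracellular water,
# neutral lipid and neutral phospholipid volumes, acidic phospholipid
# concentration (mg/g tissue), intracellular pH, and the tissue:plasma
# albumin ratio used by the protein-binding term.  Literature-standard
# adult human values; edit this file (not code) to revise the method's
# inputs.  Version: 1.
tissue,f_ew,f_iw,f_nl,f_np,ap_conc,ph_iw,protein_ratio
adipose,0.135,0.017,0.853,0.0016,0.40,7.0,0.049
bone,0.100,0.346,0.017,0.0017,0.67,7.0,0.100
brain,0.162,0.620,0.039,0.0015,0.40,7.0,0.048
gut,0.282,0.475,0.038,0.0125,2.41,7.0,0.158
heart,0.320,0.456,0.014,0.0111,2.25,7.0,0.157
kidney,0.273,0.483,0.012,0.0240,5.03,7.0,0.130
liver,0.161,0.573,0.014,0.0240,4.56,7.0,0.086
lung,0.336,0.446,0.022,0.0128,3.91,7.0,0.212
muscle,0.118,0.630,0.010,0.0072,1.53,7.0,0.064
pancreas,0.120,0.664,0.041,0.0093,1.67,7.0,0.060
skin,0.382,0.291,0.060,0.0044,1.32,7.0,0.277
spleen,0.207,0.579,0.0077,0.0113,3.18,7.0,0.097
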