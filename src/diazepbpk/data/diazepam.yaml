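# Diazepam drug-specific input parameters.
#
# Physicochemistry, binding, permeability descriptors and per-isoform
# Michaelis-Menten kinetics as compiled for the whole-body PBPK model.
# peff is the reported effective human jejunal permeability (1e-4 cm/s);
# removing it and keeping psa/hbd reproduces the same value through the
# built-in permeability correlation.
name: diazepam
molecular_weight: 284.74      # g/mol
log_p: 2.82                   # octanol:water
pka: 3.4                      # conjugate-acid pKa; essentially un-ionized at pH 7.4
ionization_class: monoprotic_base
bp_ratio: 0.58                # blood:plasma
fu_plasma: 0.03
fu_mic: 0.59
psa: 32.67                    # A^2
hbd: 0
peff: 12.434                  # 1e-4 cm/s
vss_reference: 0.66           # L/kg, reference prediction (reported range 0.59-1)

enzyme_kinetics:              # vmax pmol/min/pmol isoform, km uM
  - {isoform: CYP2B6,  pathway: n_demethylation, vmax: 3.6,   km: 113}
  - {isoform: CYP2C19, pathway: n_demethylation, vmax: 2.3,   km: 32}
  - {isoform: CYP3A4,  pathway: n_demethylation, vmax: 14.8,  km: 1828}
  - {isoform: CYP3A5,  pathway: n_demethylation, vmax: 1.8,   km: 293}
  - {isoform: CYP2B6,  pathway: hydroxylation_3, vmax: 0.1,   km: 150}
  - {isoform: CYP2C19, pathway: hydroxylation_3, vmax: 20.2,  km: 846}
  - {isoform: CYP3A4,  pathway: hydroxylation_3, vmax: 151.3, km: 2235}
  - {isoform: CYP3A5,  pathway: hydroxylation_3, vmax: 48.4,  km: 316}

routes:
  oral:
    # High-permeability compound: the whole dose is available for
    # absorption; ka derived from Peff (2*Peff/R_si, R_si = 1.75 cm).
    - {fa: 1.0, ka: 5.1157, first_pass_target: portal}
  intranasal:
    # Nasal deposition/drainage losses folded into fa; absorbed drug
    # enters venous blood directly (no first pass).
    - {fa: 0.7, ka: 1.6, first_pass_target: systemic}
    - {formulation: supersaturated_solution, fa: 0.7, ka: 3.2,
       first_pass_target: systemic}
  rectal:
    # Calibratable defaults; absorbed drug split between the portal vein
    # and systemic circulation (lower rectal veins bypass the liver).
    - {fa: 0.9, ka: 1.5, first_pass_target: portal, portal_bypass_fraction: 0.5}
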