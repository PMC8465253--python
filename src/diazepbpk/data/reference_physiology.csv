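# Reference adult physiology (70 kg male): tissue volumes (L) and
# regional blood flows (L/h).  The liver flow entry is the hepatic
# ARTERIAL flow only; gut, pancreas and spleen drain into the portal
# vein, so total liver blood flow is the sum of those four entries.
# Cardiac output is defined as the sum of all systemic flows below and
# also perfuses the lung, which sits in series.  venous/arterial/
# erythrocyte/plasma rows carry volumes only.  Literature-standard
# values; edit this file (not code) to revise.  Version: 1.
compartment,volume_L,flow_L_per_h
adipose,14.0,19.5
bone,10.5,19.5
brain,1.45,46.8
gut,1.1,58.5
heart,0.33,15.6
kidney,0.31,74.0
liver,1.8,25.4
lung,0.53,
muscle,29.0,66.3
pancreas,0.10,3.9
skin,2.6,19.5
spleen,0.19,7.8
venous_blood,3.7,
arterial_blood,1.6,
plasma,3.0,
erythrocytes,2.3,
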