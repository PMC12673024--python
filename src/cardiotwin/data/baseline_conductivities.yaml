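# Baseline tissue conductivities and normalization references.
#
# Intracellular / extracellular conductivities per axis (fiber, transverse,
# sheet-normal) in S/m.  Values follow the widely used experimentally derived
# set (Clerc-type), giving a monodomain fiber:transverse anisotropy of ~7x.
sigma_i: [0.17, 0.019, 0.019]
sigma_e: [0.62, 0.24, 0.24]
# Membrane capacitance per unit area, uF/cm^2
cm: 1.0
# Reference cell radius (um) and extracellular volume fraction at which the
# baseline conductivities apply unchanged (identity point of the mapping).
r_ref: 15.45
ecv_ref: 0.258
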