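# Physical inputs for the dilute-solution (in vitro) rate-theory chain.
# Lengths in nm, diffusion coefficients in um^2/s, rates in M^-1 s^-1,
# separations in bp.
persistence_length_a: 50.0
reaction_radius_R: 2.5
segmental_diffusion_Ds: 27.0
protein_diffusion_Dp: 61.0
measured_k1: 3.8e8
site_separation_b: 1287
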