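# Physical inputs for the crowded-nucleus (in vivo) rate-theory chain.
# Macromolecular crowding reduces protein diffusion ~4-fold and segmental
# DNA diffusion by ~5 orders of magnitude; the activation-limited rate is
# a molecular property and is carried over from the dilute-solution chain.
persistence_length_a: 50.0
reaction_radius_R: 2.5
segmental_diffusion_Ds: 5.0e-4
protein_diffusion_Dp: 15.0
measured_k1: 3.8e8
site_separation_b: 1287
carry_k_act_from: in_vitro
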