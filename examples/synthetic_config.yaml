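# Example generator configuration for `riderscore simulate` / `riderscore sweep`.
#
# ILLUSTRATIVE TRAIT PREVALENCES. No published non-rider base rates exist
# for the six diagnostic traits; every sensitivity/specificity figure
# produced from this file is conditional on the rates below.

n_individuals: 217        # size of one simulated assemblage
rider_fraction: 0.3       # latent prevalence of habitual riders

# P(trait present | rider), canonical trait order:
# entheses, ovalization, fa_lesion, platymeric, vertebral, trauma
p_trait_given_rider: [0.9, 0.7, 0.8, 0.7, 0.8, 0.3]

# P(trait present | non-rider): other strenuous activities can mimic
# each trait, so none of these is zero
p_trait_given_nonrider: [0.3, 0.1, 0.2, 0.2, 0.4, 0.1]

# completeness-linked preservation: per-skeleton completeness percent
# drawn uniformly from this range; each trait is observable with
# probability completeness/100
completeness_range: [20.0, 95.0]

sex_male_fraction: 0.67
subadult_fraction: 0.281
seed: 0
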