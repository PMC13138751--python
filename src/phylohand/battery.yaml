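# Eco-evolutionary hypothesis battery for primate handedness.
# Each hypothesis is a named covariate set; the engine treats this file as
# data, so the battery can be edited or replaced without touching code.
# Covariate codes: BM body mass, ECV endocranial volume, FRUIT/DIET diet
# proportions, IMI intermembral index, DIM body-mass sexual dimorphism,
# TOOL tool use, SUBS substrate, SOC_SYS social system, CL intrasexual
# competition level, EXT extractive foraging, SOC_LEARN social learning.
hypotheses:
  - name: brain-size
    covariates: [ECV, BM]
    applies_to: both
  - name: tool-use
    covariates: [TOOL, EXT]
    applies_to: both
  - name: postural-origins
    covariates: [IMI, SUBS]
    applies_to: both
  - name: substrate-preference
    covariates: [SUBS, BM]
    applies_to: both
  - name: foraging-ecology
    covariates: [FRUIT, DIET, EXT]
    applies_to: both
  - name: social-organisation
    covariates: [SOC_SYS, CL]
    applies_to: both
  - name: social-learning
    covariates: [SOC_LEARN, ECV]
    applies_to: both
  - name: fighting
    covariates: [DIM, CL]
    applies_to: both
  - name: TU-SH-SSH
    covariates: [TOOL, SOC_SYS, BM]
    applies_to: both
  - name: SP-SS-B-TUH
    covariates: [SUBS, SOC_SYS, IMI, TOOL, BM]
    applies_to: both
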