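# Per-trait animal-model structures: the fixed/random layout of the
# study's fitted REML (Gaussian) and MCMC (binary, logit threshold) models.
# fixed-effect names refer to phenotype-table columns; "family" is the
# micro (rearing-tank) term, "dam" the maternal-environment term.

reml:
  mo12Length: {fixed: [generation, cross_type], random: [family, animal]}
  mo12Weight: {fixed: [generation, cross_type], random: [family, animal]}
  mo12Kfact:  {fixed: [generation, cross_type], random: [family, animal]}
  mo15Length: {fixed: [generation], random: [family, animal]}
  mo15Weight: {fixed: [generation], random: [family, animal]}
  mo15Kfact:  {fixed: [generation, cross_type], random: [family, animal]}
  IGRL1:      {fixed: [generation, cross_type], random: [family, animal]}
  IGRW1:      {fixed: [generation, cross_type], random: [family, animal]}
  mo24Length: {fixed: [generation], random: [family, animal]}
  mo24Weight: {fixed: [generation], random: [family, animal]}
  mo24Kfact:  {fixed: [generation, cross_type], random: [family, animal]}
  IGRL2:      {fixed: [generation], random: [family, animal]}
  IGRW2:      {fixed: [generation, cross_type], random: [family, animal]}
  AvgPix:       {fixed: [cross_type], random: [animal]}
  CentroidSize: {fixed: [cross_type], random: [animal]}
  RelW2: {fixed: [cross_type], covariates: [CentroidSize], random: [animal]}
  RelW3: {fixed: [cross_type], random: [family, dam, animal]}
  RelW4: {fixed: [cross_type], covariates: [CentroidSize], random: [animal]}
  RelW5: {fixed: [cross_type], covariates: [CentroidSize], random: [animal]}
  RelW6: {covariates: [CentroidSize], random: [animal]}

mcmc:
  # binary life histories: logit link, residual variance fixed at 1;
  # chain settings are the study's best-fit run lengths
  LHSmolt:
    fixed: [generation]
    random: [family, animal]
    family: binary
    chain: {iterations: 1100000, burnin: 100000, thin: 1000}
  LHMature:
    fixed: [generation]
    random: [family, animal]
    family: binary
    chain: {iterations: 1100000, burnin: 100000, thin: 1000}
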