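# Literature-derived coefficients used by grassmf.indicator_derivation.
# These defaults are provisional placeholders with the right structure and
# plausible magnitudes; replace them with the coefficients of the sources a
# given study actually uses before interpreting derived indicators.
# The mineral-fertilizer availability coefficient is fixed at 1.0 by
# definition (mineral N counts as fully plant-available).
availability:            # plant-available fraction of applied total N, in [0, 1]
  mineral: 1.0
  slurry: 0.6
  solid_manure: 0.3
  compost: 0.15
n2o:                     # tier-1 style emission factors, kg N2O-N per kg N input
  ef_fertilizer: 0.01
  ef_excreta: 0.02
leaching:                # kg NO3-N leached per kg N input (provisional)
  fertilizer_coefficient: 0.1
  excreta_coefficient: 0.2
packing_density:
  clay_coefficient: 0.009   # g cm-3 per % clay (conventional default)
heavy_metal_reference:   # reference soil concentrations, mg kg-1
  cu: 40.0
  zn: 150.0
n2_fixation:
  fixed_fraction: 0.8           # fraction of legume N derived from fixation
  mass_fraction_per_cover: 0.01 # legume biomass mass fraction per % cover
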