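# Default mapping of controlled-vocabulary localization terms to
# microtubule-polarity categories, per cell-type context.
#
# minus = destinations where microtubule minus ends are enriched
#         (oocyte enrichment in the early egg-chamber, anterior cortex at
#         mid-oogenesis, apical in epithelial cells of ovary and embryo)
# plus  = destinations near microtubule plus ends (posterior pole of the
#         oocyte, pole plasm and basal enrichment in the embryo)
#
# Pole-cell annotation is cell-specific expression, not a subcellular
# localization, and is explicitly excluded from the plus category.
# Embryonic body-axis terms (anterior/posterior of the embryo) are NOT
# auto-mapped: they reflect axis polarity, not a microtubule mechanism,
# and enter only via explicit user config.
#
# Terms under "unmapped" carry no polarity; they are listed so that category
# assignment stays a total, intentional function over the vocabulary.

contexts: [germline, epithelial, embryo]

mappings:
  - {term: oocyte_enrichment, context: germline, category: minus}
  - {term: anterior_enrichment, context: germline, category: minus}
  - {term: posterior_enrichment, context: germline, category: plus}
  - {term: apical_enrichment, context: epithelial, category: minus}
  - {term: basal_enrichment, context: epithelial, category: plus}
  - {term: apical_enrichment, context: embryo, category: minus}
  - {term: basal_enrichment, context: embryo, category: plus}
  - {term: pole_plasm, context: embryo, category: plus}

excluded:
  - pole_cell

unmapped:
  - perinuclear
  - cortical_enrichment
  - cytoplasmic_foci
  - follicle_cell_restricted
  - border_cell
  - squamous_epithelium
  - nurse_cell_restricted
  - nurse_cell_nuclear
  - oocyte_nuclear
  - epithelial_nuclear
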