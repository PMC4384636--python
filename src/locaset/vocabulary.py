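"""The controlled vocabulary (CV) used to annotate FISH expression patterns.

The screen describes each (gene, probe, stage) with terms from a small
hierarchical vocabulary.  Two terms are "broad" (no detectable signal,
homogeneous/ubiquitous signal); every other term is specific and belongs to
one of three subclasses: cellular (restricted to a cell population),
subcellular (enriched in a subcellular domain), nuclear (retained in nuclei).
"""

from __future__ import annotations

NO_SIGNAL = "no_signal"
UBIQUITOUS = "ubiquitous"

# specific term -> subclass
SUBCLASS_OF: dict[str, str] = {
    # cellular: restricted to particular cell populations
    "follicle_cell_restricted": "cellular",
    "border_cell": "cellular",
    "squamous_epithelium": "cellular",
    "nurse_cell_restricted": "cellular",
    # subcellular: enriched at a subcellular site
    "oocyte_enrichment": "subcellular",
    "anterior_enrichment": "subcellular",
    "posterior_enrichment": "subcellular",
    "apical_enrichment": "subcellular",
    "basal_enrichment": "subcellular",
    "pole_plasm": "subcellular",
    "pole_cell": "subcellular",
    "perinuclear": "subcellular",
    "cortical_enrichment": "subcellular",
    "cytoplasmic_foci": "subcellular",
    # nuclear
    "nurse_cell_nuclear": "nuclear",
    "oocyte_nuclear": "nuclear",
    "epithelial_nuclear": "nuclear",
}

VOCABULARY: frozenset[str] = frozenset({NO_SIGNAL, UBIQUITOUS, *SUBCLASS_OF})

SPECIFIC_TERMS: frozenset[str] = frozenset(SUBCLASS_OF)


def is_specific(term: str) -> bool:
    return term in SPECIFIC_TERMS


def subclass_of(term: str) -> str:
    return SUBCLASS_OF[term]
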