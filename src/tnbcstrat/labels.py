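"""Label vocabularies shared across the pipeline."""

# Classifier output labels: LAR (androgen-receptor high) and the three
# TIL strata of the non-LAR cases.
CLASSIFIED_LABELS = ("LAR", "LP", "LI", "LD")

# Molecular (expression-based) labels; UNC = unclassified (no centroid
# correlation reaching significance).
MOLECULAR_LABELS = ("LAR", "IM", "BL1", "M", "UNC")

# Which molecular subtype each classified group is meant to capture.
CORRESPONDENCE = {"LAR": "LAR", "LP": "IM", "LI": "BL1", "LD": "M"}

# Nuclear staining intensity levels, in scoring order.
INTENSITY_LEVELS = ("negative", "weak", "intermediate", "strong")

# p16 staining patterns (carried through as data, never used by the rule).
P16_PATTERNS = ("negative", "weak_mosaic", "diffuse_strong")
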