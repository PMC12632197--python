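"""The five coarse nucleus classes of the PanNuke taxonomy.

Nucleus segmentation/classification tools trained on PanNuke label each
nucleus as neoplastic, inflammatory, connective, non-neoplastic epithelial or
dead.  Dead cells are excluded from every computation in this package; the
four remaining classes are the mixture components of the initial-expression
prior.
"""

NEOPLASTIC = "neoplastic"
INFLAMMATORY = "inflammatory"
CONNECTIVE = "connective"
EPITHELIAL = "non-neoplastic epithelial"
DEAD = "dead"

#: Non-dead classes, in canonical order.
CELL_TYPES: tuple[str, ...] = (NEOPLASTIC, INFLAMMATORY, CONNECTIVE, EPITHELIAL)

#: All five PanNuke classes.
ALL_CELL_TYPES: tuple[str, ...] = CELL_TYPES + (DEAD,)

#: Integer type codes used by the common HoverNet/PanNuke JSON output
#: (0 = unclassified background).
PANNUKE_CODE_TO_NAME: dict[int, str] = {
    1: NEOPLASTIC,
    2: INFLAMMATORY,
    3: CONNECTIVE,
    4: DEAD,
    5: EPITHELIAL,
}
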