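"""Cross-model twofold comparison: mouse vs rat disease models.

Compares published microvessel expression between two transgenic
amyloid-pathology models. A protein whose between-model ratio exceeds
twofold on BOTH the disease and control sides (same direction) reflects an
interspecies difference; a disease-side-only or direction-opposed excess
marks a model-specific alteration.
"""

from qtap import GroupComparisonRow, cross_model_flags
from qtap.refdata import MOUSE_MICROVESSELS, RAT_MICROVESSELS


def rows_from(table):
    rows = []
    for r in table.values():
        rows.append(GroupComparisonRow(
            protein=r.protein, control=r.control, treatment=r.disease,
            ratio=None, test=None,
            control_flag="value" if r.control else "ULQ",
            treatment_flag="value" if r.disease else "ULQ"))
    return rows


flags = cross_model_flags(rows_from(MOUSE_MICROVESSELS),
                          rows_from(RAT_MICROVESSELS), threshold=2.0)
print(f"{'protein':12s} {'rat/mouse AD':>12s} {'rat/mouse WT':>12s}  classification")
for f in flags:
    if f.classification in ("interspecies", "model-specific"):
        print(f"{f.protein:12s} {f.ratio_disease:12.2f} {f.ratio_control:12.2f}"
              f"  {f.classification}")
# FATP1 shows the model-specific signature (higher in the rat disease model
# but lower in the rat control), while e.g. Abcg2, GLUT1 and ASCT1 differ
# more than twofold in the same direction on both sides — interspecies
# differences rather than disease-model effects.
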