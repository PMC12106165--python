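"""Label codes and rendering palette shared by the generator and the baseline segmenter.

The integer label codes are the on-disk contract for mask PNGs and appear in
every JSON report header.  The RGB palette is the documented appearance model
of synthetic scenes: each mask label renders as one flat colour, and the three
pathological margin textures are skin shades whose nearest palette class is
skin, so they perturb the image without touching the label geometry.
"""

from __future__ import annotations

import numpy as np

# Integer label codes (mask PNG pixel values).
BACKGROUND = 0
SKIN = 1
FISSURE = 2
CORNEA = 3
TUMOR = 4
MARKER = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    SKIN: "skin",
    FISSURE: "fissure",
    CORNEA: "cornea",
    TUMOR: "tumor",
    MARKER: "marker",
}
LABEL_CODES = {name: code for code, name in LABEL_NAMES.items()}

# Flat RGB colour for each label.
PALETTE = {
    BACKGROUND: (0, 0, 0),
    SKIN: (205, 160, 120),
    FISSURE: (245, 245, 240),  # sclera white
    CORNEA: (70, 45, 25),      # dark iris/cornea disc
    TUMOR: (165, 40, 150),
    MARKER: (0, 90, 200),
}

# Pathology textures: drawn over skin pixels only.  Each colour's nearest
# palette class is SKIN, so palette segmentation maps textured pixels back to
# skin and the mask stays clean; the region classifiers read them from the
# image crop instead.
FOLD_COLOR = (225, 185, 150)        # epicanthal fold band
LASH_COLOR = (160, 120, 85)         # inward lash strokes (entropion/trichiasis)
ECTROPION_COLOR = (235, 95, 90)     # everted tarsal band

TEXTURE_LABELS = {
    FOLD_COLOR: SKIN,
    LASH_COLOR: SKIN,
    ECTROPION_COLOR: SKIN,
}


def classification_palette() -> tuple[np.ndarray, np.ndarray]:
    """Colour table used by the baseline segmenter.

    Returns (colors, labels): an (N, 3) float array of reference colours and
    the (N,) label code each maps to.  Texture colours alias to skin.
    """
    colors = [PALETTE[code] for code in sorted(PALETTE)]
    labels = sorted(PALETTE)
    for color, label in TEXTURE_LABELS.items():
        colors.append(color)
        labels.append(label)
    return np.asarray(colors, dtype=float), np.asarray(labels, dtype=np.uint8)
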