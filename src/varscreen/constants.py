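"""Shared constants of the screen and the classification model.

The anchored viability scale is pinned by two controls carried in every
batch: wild-type BRCA2 (functionally normal, log10 relative viability
fixed at ``log10(1.0) = 0``) and the pathogenic missense D2723H
(fixed at ``log10(0.003)``).
"""

import math

#: Anchored score of the wild-type (benign) control.
ETA_WT: float = 0.0

#: Anchored score of the pathogenic anchor control (D2723H-like).
ETA_ABN_ANCHOR: float = math.log10(0.003)

#: Conventional variant ids used for the two anchor controls.
WT_ID = "WT"
ABN_ANCHOR_ID = "D2723H"

#: Bayes-factor cut points of the five-tier functional classification:
#: fClass 1 (normal)          BF <= 0.003
#: fClass 2 (likely normal)   0.003 < BF <= 0.053
#: fClass 3 (intermediate)    0.053 < BF < 18.7
#: fClass 4 (likely abnormal) 18.7 <= BF < 350
#: fClass 5 (abnormal)        350 <= BF
FCLASS_CUTS = (0.003, 0.053, 18.7, 350.0)

#: Key functional domains of BRCA2, closed 1-based amino-acid intervals:
#: PALB2 interaction domain, DNA-binding domain, TR2 RAD51-binding domain.
KEY_DOMAINS = ((10, 40), (2481, 3186), (3269, 3305))

#: Beta prior parameters for the per-variant prior probability of being
#: functionally abnormal, keyed by Align-GVGD grade for missense variants
#: inside the key domains, with flat categories for everything else.
AGVGD_BETA_INSIDE = {
    "C65": (15.00, 3.48),
    "C55": (5.38, 2.57),
    "C45": (5.38, 2.57),
    "C35": (5.38, 2.57),
    "C25": (3.76, 9.00),
    "C15": (3.76, 9.00),
    "C0": (1.43, 73.1),
}
BETA_OUTSIDE = (1.64, 120.44)
BETA_NONSENSE = (387.0, 1.07)
BETA_NONINFORMATIVE = (1.0, 1.0)

#: Drug labels used in count tables (vehicle is DMSO).
DRUGS = ("olaparib", "niraparib", "rucaparib", "CBDCA")
VEHICLE = "DMSO"


def in_key_domain(position: int) -> bool:
    """True if a 1-based protein position lies inside a key domain
    (boundaries inclusive)."""
    return any(lo <= position <= hi for lo, hi in KEY_DOMAINS)
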