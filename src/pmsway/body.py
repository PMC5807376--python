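"""Marker-set conventions, anthropometric template and segment mass table.

The default marker set mimics a full-body plug-in-gait-style configuration
without hand markers: 15 bilateral label pairs (``L``/``R`` prefix) plus 7
unpaired trunk/head labels, 37 markers total.  One of the unpaired labels,
``BACK`` (an off-center mid-back marker), is not bilaterally symmetric and is
dropped by the default analysis policy.

Relative segment masses follow the classic anthropometric fractions
(head+neck 0.081, trunk 0.497, each thigh 0.100, each shank 0.0465, each
foot 0.0145, each upper arm 0.028, each forearm+hand 0.022); a segment's
fraction is split equally among the markers representing it.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError

__all__ = [
    "PAIR_STEMS",
    "MIDLINE_LABELS",
    "NON_SYMMETRIC_LABELS",
    "SEGMENT_MASS_FRACTIONS",
    "TEMPLATE_HEIGHT",
    "full_marker_labels",
    "template_posture",
    "segment_of",
]

#: Bilateral marker stems in canonical order; actual labels are "L"+stem, "R"+stem.
PAIR_STEMS = [
    "FHD", "BHD", "SHO", "UPA", "ELB", "FRA", "WRA",
    "ASI", "PSI", "THI", "KNE", "TIB", "ANK", "HEE", "TOE",
]

#: Unpaired labels. BACK sits off the midline (over the right scapula).
MIDLINE_LABELS = ["HEAD", "C7", "CLAV", "STRN", "T10", "SACR", "BACK"]

#: Unpaired labels without a bilateral mirror placement; the default
#: selection policy removes these before the decomposition.
NON_SYMMETRIC_LABELS = ("BACK",)

#: Relative mass of each body segment (fraction of total body mass).
SEGMENT_MASS_FRACTIONS = {
    "head_neck": 0.081,
    "trunk": 0.497,
    "upper_arm_L": 0.028,
    "upper_arm_R": 0.028,
    "forearm_hand_L": 0.022,
    "forearm_hand_R": 0.022,
    "thigh_L": 0.100,
    "thigh_R": 0.100,
    "shank_L": 0.0465,
    "shank_R": 0.0465,
    "foot_L": 0.0145,
    "foot_R": 0.0145,
}

_STEM_SEGMENT = {
    "FHD": "head_neck", "BHD": "head_neck",
    "SHO": "trunk", "ASI": "trunk", "PSI": "trunk",
    "UPA": "upper_arm", "ELB": "upper_arm",
    "FRA": "forearm_hand", "WRA": "forearm_hand",
    "THI": "thigh", "KNE": "thigh",
    "TIB": "shank", "ANK": "shank",
    "HEE": "foot", "TOE": "foot",
}

_MIDLINE_SEGMENT = {
    "HEAD": "head_neck", "C7": "head_neck",
    "CLAV": "trunk", "STRN": "trunk", "T10": "trunk",
    "SACR": "trunk", "BACK": "trunk",
}

#: Stature of the template posture below (meters).
TEMPLATE_HEIGHT = 1.70

# Template standing posture for a 1.70 m subject, tandem stance with the
# right foot in front.  (x anterior, y leftward, z up), meters.
_TEMPLATE = {
    "HEAD": (0.00, 0.00, 1.70),
    "LFHD": (0.07, 0.06, 1.63), "RFHD": (0.07, -0.06, 1.63),
    "LBHD": (-0.07, 0.06, 1.60), "RBHD": (-0.07, -0.06, 1.60),
    "C7": (-0.05, 0.00, 1.45),
    "CLAV": (0.05, 0.00, 1.42),
    "STRN": (0.08, 0.00, 1.25),
    "T10": (-0.09, 0.00, 1.22),
    "BACK": (-0.10, 0.05, 1.35),
    "SACR": (-0.11, 0.00, 1.00),
    "LSHO": (0.00, 0.18, 1.40), "RSHO": (0.00, -0.18, 1.40),
    "LUPA": (0.01, 0.20, 1.22), "RUPA": (0.01, -0.20, 1.22),
    "LELB": (0.02, 0.21, 1.10), "RELB": (0.02, -0.21, 1.10),
    "LFRA": (0.06, 0.20, 1.01), "RFRA": (0.06, -0.20, 1.01),
    "LWRA": (0.09, 0.17, 0.94), "RWRA": (0.09, -0.17, 0.94),
    "LASI": (0.09, 0.12, 0.96), "RASI": (0.09, -0.12, 0.96),
    "LPSI": (-0.08, 0.05, 0.98), "RPSI": (-0.08, -0.05, 0.98),
    "LTHI": (0.04, 0.14, 0.70), "RTHI": (0.09, -0.14, 0.72),
    "LKNE": (-0.02, 0.10, 0.48), "RKNE": (0.10, -0.10, 0.49),
    "LTIB": (-0.04, 0.09, 0.30), "RTIB": (0.11, -0.09, 0.31),
    "LANK": (-0.11, 0.05, 0.08), "RANK": (0.12, -0.05, 0.08),
    "LHEE": (-0.17, 0.04, 0.03), "RHEE": (0.04, -0.03, 0.03),
    "LTOE": (0.02, 0.04, 0.02), "RTOE": (0.26, -0.03, 0.02),
}


def full_marker_labels() -> list[str]:
    """The canonical 37-label set: 15 L/R pairs followed by 7 unpaired labels."""
    labels = []
    for stem in PAIR_STEMS:
        labels.append("L" + stem)
        labels.append("R" + stem)
    labels.extend(MIDLINE_LABELS)
    return labels


def segment_of(label: str) -> str:
    """Map a marker label to its body segment key."""
    if label in _MIDLINE_SEGMENT:
        return _MIDLINE_SEGMENT[label]
    side = label[0]
    stem = label[1:]
    if side in ("L", "R") and stem in _STEM_SEGMENT:
        seg = _STEM_SEGMENT[stem]
        if seg in ("head_neck", "trunk"):
            return seg
        return f"{seg}_{side}"
    raise ConfigError(f"unknown marker label {label!r}")


def template_posture(labels: list[str]) -> np.ndarray:
    """Template coordinates (meters, 1.70 m stature) for the given labels."""
    try:
        return np.array([_TEMPLATE[lab] for lab in labels], dtype=float)
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise ConfigError(f"no template coordinates for label {exc}") from exc
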