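"""IMGT physicochemical classes of the 20 standard amino acids.

Classes follow the IMGT amino-acid classification (IMGT Aide-mémoire,
"Amino acids"): hydropathy in 3 classes, volume in 5 classes (Å³
ranges), chemical characteristics in 7 classes.  Each classification
partitions the 20 one-letter amino acids.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HYDROPATHY = {
    "hydrophobic": set("ACFILMVW"),
    "neutral": set("GHPSTY"),
    "hydrophilic": set("DEKNQR"),
}

# volume classes, Å³: very small 60-90, small 108-117, medium 138-154,
# large 162-174, very large 189-228
VOLUME = {
    "very_small": set("AGS"),
    "small": set("CDNPT"),
    "medium": set("EHQV"),
    "large": set("IKLMR"),
    "very_large": set("FWY"),
}

CHEMICAL = {
    "aliphatic": set("AGILPV"),
    "aromatic": set("FWY"),
    "sulfur": set("CM"),
    "hydroxyl": set("ST"),
    "basic": set("HKR"),
    "acidic": set("DE"),
    "amide": set("NQ"),
}


def _class_of(aa: str, classification: dict) -> str:
    for name, members in classification.items():
        if aa in members:
            return name
    raise KeyError(aa)


def hydropathy_class(aa: str) -> str:
    return _class_of(aa, HYDROPATHY)


def volume_class(aa: str) -> str:
    return _class_of(aa, VOLUME)


def chemical_class(aa: str) -> str:
    return _class_of(aa, CHEMICAL)


def changes_class(a: str, b: str, classification: dict) -> bool:
    """True when the substitution a→b crosses class boundaries."""
    return _class_of(a, classification) != _class_of(b, classification)
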