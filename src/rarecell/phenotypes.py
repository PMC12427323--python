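"""The 8 immunofluorescence phenotypes of a DAPI+ event.

Every segmented event is nucleated (DAPI+); its phenotype is determined by which
of the three marker channels (CK, V, CD) it is positive for, giving the 2^3 = 8
channel types: D, D|CK, D|V, D|CD, D|CK|V, D|CK|CD, D|V|CD, D|CK|V|CD.
"""

from __future__ import annotations

MARKERS: tuple[str, ...] = ("CK", "V", "CD")


def assign_cell_type(ck_positive: bool, v_positive: bool, cd_positive: bool) -> str:
    """Map the three marker calls of a DAPI+ event to its channel-type label.

    Total and deterministic: each of the 8 boolean combinations maps to a
    distinct label; all-negative gives the DAPI-only type ``"D"``.
    """
    parts = ["D"]
    for name, flag in zip(MARKERS, (ck_positive, v_positive, cd_positive)):
        if flag:
            parts.append(name)
    return "|".join(parts)


#: The 8 phenotype labels in canonical order (by number of positive markers,
#: then marker order CK, V, CD).
CELL_TYPES: tuple[str, ...] = (
    "D",
    "D|CK",
    "D|V",
    "D|CD",
    "D|CK|V",
    "D|CK|CD",
    "D|V|CD",
    "D|CK|V|CD",
)


def positivity_of(cell_type: str) -> tuple[bool, bool, bool]:
    """Inverse of :func:`assign_cell_type`: (CK, V, CD) positivity of a label."""
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}")
    parts = set(cell_type.split("|"))
    return tuple(m in parts for m in MARKERS)  # type: ignore[return-value]
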