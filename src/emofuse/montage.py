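"""Electrode montage conventions.

A fixed 30-channel 10-20 arrangement: twelve left/right symmetric pairs
(used by the hemispheric-asymmetry features) plus six midline electrodes.
"""

from __future__ import annotations

#: Left/right symmetric electrode pairs, in the order the differential
#: spectral features are laid out (pair-major).
SYMMETRIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"),
    ("F7", "F8"),
    ("F3", "F4"),
    ("FT7", "FT8"),
    ("FC3", "FC4"),
    ("T3", "T4"),
    ("C3", "C4"),
    ("TP7", "TP8"),
    ("CP3", "CP4"),
    ("T5", "T6"),
    ("P3", "P4"),
    ("O1", "O2"),
)

#: Midline electrodes completing the 30-channel montage.
MIDLINE: tuple[str, ...] = ("FZ", "FCZ", "CZ", "CPZ", "PZ", "OZ")

#: Default channel ordering: left, right of each pair in pair order, then midline.
DEFAULT_MONTAGE: tuple[str, ...] = tuple(
    ch for pair in SYMMETRIC_PAIRS for ch in pair
) + MIDLINE

assert len(DEFAULT_MONTAGE) == 30


def channel_index(channel_names: list[str] | tuple[str, ...]) -> dict[str, int]:
    """Map upper-cased channel label -> position."""
    return {name.upper(): i for i, name in enumerate(channel_names)}
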