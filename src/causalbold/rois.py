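"""Canonical region-of-interest vocabulary.

The analysis operates on 18 task-activated regions spanning the
"social brain" and visuospatial systems.  All matrices, feature names
and file headers use this fixed ordering.
"""

from __future__ import annotations

#: Fixed ROI ordering used for every connectivity matrix and feature name.
CANONICAL_ROIS: tuple[str, ...] = (
    "SMA",    # supplementary motor area
    "LIFG",   # left inferior frontal gyrus
    "RIFG",   # right inferior frontal gyrus
    "LPRCN",  # left precentral cortex
    "RPRCN",  # right precentral cortex
    "LMTG",   # left middle temporal gyrus
    "RMTG",   # right middle temporal gyrus
    "RSTG",   # right superior temporal gyrus
    "LIPL",   # left inferior parietal lobule
    "RIPL",   # right inferior parietal lobule
    "LFFG",   # left fusiform gyrus
    "RFFG",   # right fusiform gyrus
    "LSPL",   # left superior parietal lobule
    "RSPL",   # right superior parietal lobule
    "LMOG",   # left middle occipital gyrus
    "RMOG",   # right middle occipital gyrus
    "LTPJ",   # left temporo-parietal junction
    "RTPJ",   # right temporo-parietal junction
)

#: Directed-path feature separator, e.g. ``"LMTG->LTPJ"``.
PATH_SEP = "->"

#: Undirected-pair feature separator, e.g. ``"LMTG<->LTPJ"``.
PAIR_SEP = "<->"


def roi_labels(n_rois: int) -> tuple[str, ...]:
    """Return ``n_rois`` labels: the canonical names, or ``ROI01``-style
    placeholders when more regions than the canonical 18 are requested."""
    if n_rois <= len(CANONICAL_ROIS):
        return CANONICAL_ROIS[:n_rois]
    return tuple(f"ROI{i + 1:02d}" for i in range(n_rois))


def path_name(source: str, sink: str) -> str:
    """Directed path feature name ``SRC->SNK``."""
    return f"{source}{PATH_SEP}{sink}"


def parse_path_name(name: str) -> tuple[str, str]:
    """Invert :func:`path_name`."""
    source, sink = name.split(PATH_SEP)
    return source, sink


def pair_name(a: str, b: str) -> str:
    """Undirected pair feature name ``A<->B``."""
    return f"{a}{PAIR_SEP}{b}"


def parse_pair_name(name: str) -> tuple[str, str]:
    """Invert :func:`pair_name`."""
    a, b = name.split(PAIR_SEP)
    return a, b
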