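"""DRACH motif classification and summaries.

m6A sites sit in a pentamer with the methylated A at the center.  The DRACH
consensus constrains the other four positions: D = {A,G,T}, R = {A,G},
position 4 = C, H = {A,C,T} (U in RNA notation maps to T, since analysis is
in reference space).  The 256 center-A pentamers partition into four classes
by mismatch count against (D, R, ·, C, H):

* ``DRACH``        — 0 mismatches (18 pentamers);
* ``DRACN_1mm``    — the single mismatch is at position 5 (6 pentamers);
* ``nonDRACN_1mm`` — the single mismatch is at position 1, 2 or 4 (78);
* ``multi_mm``     — two or more mismatches (154).

"DRAC" — the set retained for all downstream analyses — is the union of the
first two classes: first four bases conform, free fifth base (24 pentamers).
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

DRACH = "DRACH"
DRACN_1MM = "DRACN_1mm"
NON_DRACN_1MM = "nonDRACN_1mm"
MULTI_MM = "multi_mm"

MOTIF_CLASSES = (DRACH, DRACN_1MM, NON_DRACN_1MM, MULTI_MM)
DRAC_CLASSES = frozenset({DRACH, DRACN_1MM})

_ALPHABET = frozenset("ACGT")
# allowed bases at positions 1,2,4,5 (position 3 is the fixed center A)
_D = frozenset("AGT")
_R = frozenset("AG")
_C = frozenset("C")
_H = frozenset("ACT")
_POSITION_SETS = (_D, _R, _C, _H)  # for pentamer indices 0, 1, 3, 4


def classify_motif(pentamer: str) -> str:
    """Classify a center-A pentamer against the DRACH consensus."""
    if len(pentamer) != 5:
        raise InputError(f"pentamer must have length 5, got {pentamer!r}")
    pentamer = pentamer.upper()
    if any(b not in _ALPHABET for b in pentamer):
        raise InputError(f"pentamer {pentamer!r} outside the ACGT alphabet")
    if pentamer[2] != "A":
        raise InputError(f"pentamer {pentamer!r} does not have a central A")
    mismatch_positions = [
        idx
        for idx, allowed in zip((0, 1, 3, 4), _POSITION_SETS)
        if pentamer[idx] not in allowed
    ]
    if not mismatch_positions:
        return DRACH
    if len(mismatch_positions) == 1:
        return DRACN_1MM if mismatch_positions[0] == 4 else NON_DRACN_1MM
    return MULTI_MM


def classify_motifs(pentamers: Iterable[str]) -> List[str]:
    return [classify_motif(p) for p in pentamers]


def is_drac(pentamer: str) -> bool:
    """True if the first four bases conform to DRAC (free fifth base)."""
    return classify_motif(pentamer) in DRAC_CLASSES


def all_center_a_pentamers() -> List[str]:
    return [
        f"{a}{b}A{c}{d}"
        for a, b, c, d in itertools.product("ACGT", repeat=4)
    ]


def motif_partition_counts() -> Dict[str, int]:
    """Class sizes over the full universe of 256 center-A pentamers."""
    counts = {cls: 0 for cls in MOTIF_CLASSES}
    for pentamer in all_center_a_pentamers():
        counts[classify_motif(pentamer)] += 1
    return counts


def drac_pentamers() -> List[str]:
    """The 24 pentamers whose first four bases conform to DRAC."""
    return [p for p in all_center_a_pentamers() if is_drac(p)]


def restrict_to_drac(sites: pd.DataFrame) -> pd.DataFrame:
    """Keep only sites in DRAC context (classes DRACH and DRACN_1mm)."""
    if sites.empty:
        return sites.copy()
    return sites[sites["motif_class"].isin(DRAC_CLASSES)].copy()


def motif_summary(
    sites: pd.DataFrame, top_k: int = 15
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pentamer frequencies, per-class level distribution, and top-k table.

    Returns ``(frequencies, class_levels, top)``.  Frequencies sum to 1; the
    top-k table is ordered by (count desc, pentamer lexicographic) so ties
    break deterministically.
    """
    if sites.empty:
        empty_freq = pd.DataFrame(columns=["pentamer", "count", "frequency"])
        empty_cls = pd.DataFrame(
            columns=["motif_class", "n", "median", "q25", "q75"]
        )
        return empty_freq, empty_cls, empty_freq.copy()

    counts = (
        sites.groupby("pentamer").size().rename("count").reset_index()
    )
    counts["frequency"] = counts["count"] / counts["count"].sum()
    counts = counts.sort_values(
        ["count", "pentamer"], ascending=[False, True]
    ).reset_index(drop=True)

    cls = (
        sites.groupby("motif_class")["level"]
        .agg(
            n="size",
            median="median",
            q25=lambda x: float(np.quantile(x, 0.25)),
            q75=lambda x: float(np.quantile(x, 0.75)),
        )
        .reset_index()
    )
    return counts, cls, counts.head(top_k).copy()


def position_frequency_matrix(sites: pd.DataFrame) -> pd.DataFrame:
    """Base frequencies at each of the five pentamer positions."""
    if sites.empty:
        return pd.DataFrame(
            0.0, index=list("ACGT"), columns=[f"pos{i}" for i in range(1, 6)]
        )
    mat = np.zeros((4, 5))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for pentamer in sites["pentamer"]:
        for j, base in enumerate(pentamer):
            mat[base_index[base], j] += 1
    mat /= len(sites)
    return pd.DataFrame(
        mat, index=list("ACGT"), columns=[f"pos{i}" for i in range(1, 6)]
    )
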