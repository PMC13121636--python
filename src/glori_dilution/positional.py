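"""Metagene coordinates and stop-codon-centered profiles.

The metagene coordinate rescales each transcript region to unit length:
UTR5 maps to [0,1), CDS to [1,2), UTR3 to [2,3), so x = 2.0 is the first
base after the stop codon on every transcript regardless of its segment
lengths.  Region-normalized (not length-proportional) scaling matches the
conventional three-panel metagene layout.  Sites are counted equally by
default; ``weights`` allows methylation-level weighting.

The stop-codon profile bins differential sites by their nucleotide offset
from the CDS/3'-UTR junction (negative offsets = CDS side; the first 3'-UTR
base is offset 0) and reports the mean methylation difference per bin.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation
from .errors import InputError


def metagene_coordinate(sites: pd.DataFrame, annotation: Annotation) -> pd.Series:
    """Normalized transcript coordinate x in [0, 3) for each site."""
    xs = []
    for row in sites.itertuples(index=False):
        model = annotation.locate(row.contig, row.pos0, row.strand)
        if model is None:
            raise InputError(
                f"site {row.contig}:{row.pos0}:{row.strand} outside any transcript"
            )
        tpos = model.to_transcript_pos(row.pos0)
        bounds = (0, model.utr5_len, model.utr5_len + model.cds_len)
        lengths = (model.utr5_len, model.cds_len, model.utr3_len)
        if tpos < bounds[1]:
            region_index = 0
        elif tpos < bounds[2]:
            region_index = 1
        else:
            region_index = 2
        if lengths[region_index] <= 0:
            raise InputError(
                f"zero-length region on transcript {model.transcript_id}"
            )
        offset = tpos - bounds[region_index]
        xs.append(region_index + offset / lengths[region_index])
    return pd.Series(xs, index=sites.index, name="metagene_x")


def metagene_density(
    x: pd.Series, n_bins: int = 90, weights: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Binned density over [0, 3) normalized to integrate to 1."""
    if len(x) == 0:
        raise InputError("metagene density needs at least one coordinate")
    w = None if weights is None else np.asarray(weights, dtype=float)
    hist, edges = np.histogram(
        np.asarray(x, dtype=float), bins=n_bins, range=(0.0, 3.0),
        weights=w, density=True,
    )
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "x_mid": 0.5 * (edges[:-1] + edges[1:]),
            "density": hist,
        }
    )


def stop_offsets(sites: pd.DataFrame, annotation: Annotation) -> pd.Series:
    """Nucleotide offset of each site from the CDS/3'-UTR junction."""
    offsets = []
    for row in sites.itertuples(index=False):
        model = annotation.locate(row.contig, row.pos0, row.strand)
        if model is None:
            raise InputError(
                f"site {row.contig}:{row.pos0}:{row.strand} outside any transcript"
            )
        offsets.append(model.stop_offset(model.to_transcript_pos(row.pos0)))
    return pd.Series(offsets, index=sites.index, name="stop_offset")


def stop_codon_profile(
    diff_sites: pd.DataFrame,
    annotation: Annotation,
    window: int = 400,
    bin_width: int = 20,
) -> pd.DataFrame:
    """Mean methylation difference in bins around the stop codon.

    ``diff_sites`` must carry a ``delta`` column.  Bins tile [-window,
    +window) exactly; sites outside the window are excluded.
    """
    if window % bin_width != 0:
        raise InputError("window must be a multiple of bin_width")
    edges = np.arange(-window, window + bin_width, bin_width)
    if diff_sites.empty:
        return pd.DataFrame(
            {
                "bin_start": edges[:-1],
                "bin_end": edges[1:],
                "mean_delta": np.full(len(edges) - 1, np.nan),
                "n_sites": np.zeros(len(edges) - 1, dtype=int),
            }
        )
    offsets = stop_offsets(diff_sites, annotation).to_numpy()
    delta = diff_sites["delta"].to_numpy(dtype=float)
    inside = (offsets >= -window) & (offsets < window)
    offsets, delta = offsets[inside], delta[inside]
    idx = ((offsets + window) // bin_width).astype(int)
    n_bins = len(edges) - 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=delta, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean_delta": means,
            "n_sites": counts,
        }
    )
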