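"""Per-site bulk-segregant statistics and kernel smoothing.

Three complementary statistics are computed from the polarized allele depths
of the two bulks at every retained site:

* ``delta`` — difference in tall-allele frequency between tall and dwarf
  bulk (tall minus dwarf), in [-1, 1];
* ``g`` — the 2x2 allele-count G statistic (log-likelihood-ratio test of
  allele-by-bulk association), smoothed into G';
* ``ed``/``ed4`` — Euclidean distance between bulk allele-frequency vectors
  (= sqrt(2)*|delta| for biallelic sites) and its fourth power.

Smoothing uses a tricube kernel of half-width ``h`` bp evaluated at every
variant site, computed per chromosome, with windows truncated at chromosome
ends.  ED is raised to the fourth power *before* smoothing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .varfilter import BulkVariantTable

#: default total window span in bp (kernel half-width = half of this)
DEFAULT_WINDOW_BP = 1_000_000

STAT_COLUMNS = (
    "chrom",
    "pos",
    "index_dwarf",
    "index_tall",
    "delta",
    "g",
    "ed",
    "ed4",
    "gprime",
    "delta_smoothed",
    "ed4_smoothed",
)


def snp_index(
    tall_dwarf: np.ndarray,
    other_dwarf: np.ndarray,
    tall_tall: np.ndarray,
    other_tall: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tall-allele frequency in each bulk and their difference.

    Arguments are read counts (tall-parent allele vs the other allele) in
    the dwarf and tall bulks.  Zero-depth sites yield NaN.
    """
    td, od = np.asarray(tall_dwarf, float), np.asarray(other_dwarf, float)
    tt, ot = np.asarray(tall_tall, float), np.asarray(other_tall, float)
    nd, nt = td + od, tt + ot
    with np.errstate(invalid="ignore", divide="ignore"):
        index_dwarf = np.where(nd > 0, td / nd, np.nan)
        index_tall = np.where(nt > 0, tt / nt, np.nan)
    return index_dwarf, index_tall, index_tall - index_dwarf


def g_statistic(
    tall_dwarf: np.ndarray,
    other_dwarf: np.ndarray,
    tall_tall: np.ndarray,
    other_tall: np.ndarray,
) -> np.ndarray:
    """G = 2 * sum n_i * ln(n_i / nhat_i) over the 2x2 read-count table.

    Expected cell counts ``nhat`` come from the row/column margins
    (independence model); cells with n=0 contribute 0.  Zero grand totals
    yield NaN (the site carries no information).
    """
    cells = np.stack(
        [np.asarray(x, float) for x in (tall_dwarf, other_dwarf, tall_tall, other_tall)]
    )
    n_dwarf = cells[0] + cells[1]
    n_tall = cells[2] + cells[3]
    n_tallallele = cells[0] + cells[2]
    n_other = cells[1] + cells[3]
    total = n_dwarf + n_tall
    rows = np.stack([n_dwarf, n_dwarf, n_tall, n_tall])
    cols = np.stack([n_tallallele, n_other, n_tallallele, n_other])
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = rows * cols / total
        terms = np.where(cells > 0, cells * np.log(cells / expected), 0.0)
    g = 2.0 * terms.sum(axis=0)
    g = np.where(total > 0, np.maximum(g, 0.0), np.nan)
    return g


def euclidean_distance(delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ED over the two allele frequencies and its fourth power.

    For a biallelic site the frequency difference of the second allele is
    the negative of the first, so ED = sqrt(2) * |delta|.
    """
    ed = np.sqrt(2.0) * np.abs(np.asarray(delta, float))
    return ed, ed**4


def tricube_weights(distances: np.ndarray, h: float) -> np.ndarray:
    """Tricube kernel weight (1 - (d/h)^3)^3 for |d| <= h, else 0."""
    u = np.abs(np.asarray(distances, float)) / h
    w = (1.0 - u**3) ** 3
    return np.where(u <= 1.0, w, 0.0)


def smooth(
    positions: Sequence[int],
    values: Sequence[float],
    h: float,
    chroms: Sequence[str] | None = None,
) -> np.ndarray:
    """Tricube-kernel smoothing of a per-site track.

    The smoothed value at site *i* is the kernel-weighted mean of raw values
    at sites within ``h`` bp on the same chromosome (windows truncate at
    ends).  Positions must be sorted within each chromosome.  NaN raw values
    are ignored in the average.
    """
    if h <= 0:
        raise ValueError("kernel half-width h must be positive")
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if len(pos) == 0:
        return np.empty(0)
    if chroms is None:
        groups = [np.arange(len(pos))]
    else:
        chroms = np.asarray(chroms)
        groups = [np.flatnonzero(chroms == c) for c in pd.unique(chroms)]

    out = np.full(len(pos), np.nan)
    for idx in groups:
        p, v = pos[idx], val[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError("positions must be sorted within each chromosome")
        lo = np.searchsorted(p, p - h, side="left")
        hi = np.searchsorted(p, p + h, side="right")
        sm = np.empty(len(p))
        for i in range(len(p)):
            w = tricube_weights(p[lo[i]:hi[i]] - p[i], h)
            vv = v[lo[i]:hi[i]]
            ok = ~np.isnan(vv)
            denom = w[ok].sum()
            sm[i] = np.dot(w[ok], vv[ok]) / denom if denom > 0 else np.nan
        out[idx] = sm
    return out


def compute_stats(
    table: BulkVariantTable, window_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """All three statistics plus smoothed tracks for a polarized table.

    Returns a frame with :data:`STAT_COLUMNS`; ``gprime``,
    ``delta_smoothed`` and ``ed4_smoothed`` use a tricube kernel of
    half-width ``window_bp / 2``.  Sites with zero depth in either bulk are
    dropped (logged by count in the returned frame's attrs).
    """
    if not table.is_polarized:
        raise ValueError("compute_stats requires a polarized table")
    df = table.df
    td = table.tall_counts("bulk_dwarf").to_numpy(float)
    tt = table.tall_counts("bulk_tall").to_numpy(float)
    nd = table.depth("bulk_dwarf").to_numpy(float)
    nt = table.depth("bulk_tall").to_numpy(float)
    od, ot = nd - td, nt - tt

    usable = (nd > 0) & (nt > 0)
    n_dropped = int((~usable).sum())

    index_dwarf, index_tall, delta = snp_index(td, od, tt, ot)
    g = g_statistic(td, od, tt, ot)
    ed, ed4 = euclidean_distance(delta)

    stats = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "index_dwarf": index_dwarf,
            "index_tall": index_tall,
            "delta": delta,
            "g": g,
            "ed": ed,
            "ed4": ed4,
        }
    )[usable].reset_index(drop=True)

    h = window_bp / 2.0
    pos = stats["pos"].to_numpy()
    chroms = stats["chrom"].to_numpy()
    stats["gprime"] = smooth(pos, stats["g"].to_numpy(), h, chroms)
    stats["delta_smoothed"] = smooth(pos, stats["delta"].to_numpy(), h, chroms)
    stats["ed4_smoothed"] = smooth(pos, stats["ed4"].to_numpy(), h, chroms)
    stats.attrs["window_bp"] = window_bp
    stats.attrs["dropped_zero_depth"] = n_dropped
    return stats
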