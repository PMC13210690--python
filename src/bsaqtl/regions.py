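"""Candidate-region calling, cross-method consensus and interval reporting.

A statistic track is thresholded at an empirical genome-wide quantile
(default 0.999, linear interpolation between order statistics; absolute
values for the signed delta track).  Maximal runs of consecutive
above-threshold sites become candidate regions; runs separated by at most
``merge_gap`` bp may be merged; regions with fewer than ``min_sites``
above-threshold sites (default 10) are discarded.  Region bounds are the
positions of the outermost above-threshold sites.

Coordinates are 1-based fully closed throughout; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: statistic column -> whether thresholding uses absolute values
SIGNED_TRACKS = {"delta_smoothed": True, "gprime": False, "ed4_smoothed": False}

#: conventional method names for the three smoothed tracks
TRACK_METHODS = {
    "ed4_smoothed": "ED",
    "gprime": "Gprime",
    "delta_smoothed": "Index-slid",
}

_UNIT_DIVISOR = {"bp": 1, "kb": 1_000, "Mb": 1_000_000}


@dataclass
class Threshold:
    statistic: str
    q: float
    cutoff: float


@dataclass
class CandidateRegion:
    """Contiguous interval of above-threshold sites (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    methods: frozenset = frozenset()
    n_sites_above: int = 0
    total_snps: Optional[int] = None
    total_indels: Optional[int] = None
    effective_snps: Optional[int] = None
    effective_indels: Optional[int] = None
    annotated_genes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "CandidateRegion") -> int:
        """Closed-interval intersection length in bp (0 when disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class ConsensusEntry:
    """One input region annotated with its cross-method support."""

    region: CandidateRegion
    method: str
    support_methods: frozenset
    #: partner overlaps: (method, partner region, |∩|/|self|, |∩|/|partner|)
    partners: list = field(default_factory=list)

    @property
    def n_methods(self) -> int:
        return len(self.support_methods)


def compute_threshold(
    values: Sequence[float], q: float = 0.999, use_abs: bool = False,
    statistic: str = "",
) -> Threshold:
    """Empirical quantile threshold (linear interpolation convention)."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("cannot compute a threshold on an empty track")
    if not 0 < q <= 1:
        raise ValueError("quantile level must lie in (0, 1]")
    if use_abs:
        v = np.abs(v)
    return Threshold(statistic=statistic, q=q, cutoff=float(np.quantile(v, q)))


def call_regions(
    stats: pd.DataFrame,
    column: str,
    threshold: Threshold | float,
    min_sites: int = 10,
    merge_gap: int = 0,
    use_abs: Optional[bool] = None,
    method: Optional[str] = None,
) -> list[CandidateRegion]:
    """Candidate regions from one smoothed track.

    ``stats`` must carry ``chrom``, ``pos`` and ``column``, sorted by
    (chrom, pos).  A site is above threshold when its (absolute, for signed
    tracks) smoothed value strictly exceeds the cutoff.  Runs separated by
    at most ``merge_gap`` bp of sub-threshold territory are merged before
    the ``min_sites`` rule is applied.
    """
    cutoff = threshold.cutoff if isinstance(threshold, Threshold) else float(threshold)
    if use_abs is None:
        use_abs = SIGNED_TRACKS.get(column, False)
    if method is None:
        method = TRACK_METHODS.get(column, column)

    out: list[CandidateRegion] = []
    for chrom, sub in stats.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        val = sub[column].to_numpy(float)
        if use_abs:
            val = np.abs(val)
        above = val > cutoff
        runs = _runs(above)
        merged = _merge_runs(runs, pos, merge_gap)
        for lo, hi in merged:  # site-index bounds, inclusive
            n_above = int(above[lo : hi + 1].sum())
            if n_above < min_sites:
                continue
            above_idx = np.flatnonzero(above[lo : hi + 1]) + lo
            out.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start=int(pos[above_idx[0]]),
                    end=int(pos[above_idx[-1]]),
                    methods=frozenset({method}),
                    n_sites_above=n_above,
                )
            )
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _merge_runs(
    runs: list[tuple[int, int]], pos: np.ndarray, merge_gap: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for lo, hi in runs[1:]:
        plo, phi = merged[-1]
        if pos[lo] - pos[phi] <= merge_gap:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def consensus(
    regions_by_method: Mapping[str, Sequence[CandidateRegion]],
) -> list[ConsensusEntry]:
    """Annotate every region with the methods whose regions overlap it.

    Two regions support each other when they share >= 1 bp of closed-interval
    intersection.  The output contains exactly one entry per input region
    (nothing invented or lost), ordered by (support count desc, chrom,
    start); each partner is reported with both overlap fractions so callers
    can apply a reciprocal-overlap criterion.
    """
    flat = [
        (meth, reg)
        for meth, regs in regions_by_method.items()
        for reg in regs
    ]
    entries = []
    for meth, reg in flat:
        partners = []
        support = {meth}
        for other_meth, other in flat:
            if other is reg and other_meth == meth:
                continue
            ov = reg.overlap(other)
            if ov >= 1:
                partners.append(
                    (other_meth, other, ov / reg.length, ov / other.length)
                )
                support.add(other_meth)
        entries.append(
            ConsensusEntry(
                region=replace(reg, methods=frozenset(support)),
                method=meth,
                support_methods=frozenset(support),
                partners=partners,
            )
        )
    entries.sort(key=lambda e: (-e.n_methods, e.region.chrom, e.region.start))
    return entries


def reciprocal_pairs(
    entries: Iterable[ConsensusEntry], min_reciprocal: float = 1.0
) -> list[tuple]:
    """Unordered cross-method region pairs with reciprocal overlap >= cutoff.

    Reciprocal overlap of a pair is the smaller of the two mutual overlap
    fractions; 1.0 means coordinate-identical intervals.
    """
    seen = set()
    pairs = []
    for e in entries:
        for other_meth, other, f_self, f_other in e.partners:
            if other_meth == e.method:
                continue
            rec = min(f_self, f_other)
            if rec < min_reciprocal:
                continue
            key = frozenset(
                [
                    (e.method, e.region.chrom, e.region.start, e.region.end),
                    (other_meth, other.chrom, other.start, other.end),
                ]
            )
            if key in seen:
                continue
            seen.add(key)
            pairs.append((e.region, e.method, other, other_meth, rec))
    return pairs


def interval_span(start: int, end: int, unit: str = "bp") -> float:
    """Length of the closed interval [start, end] in the requested unit.

    kb/Mb results are rounded half-up to 2 decimals, matching conventional
    interval reporting; bp results are exact integers.
    """
    if start > end:
        raise ValueError("interval start must not exceed end")
    if unit not in _UNIT_DIVISOR:
        raise ValueError(f"unknown unit {unit!r}; expected one of {list(_UNIT_DIVISOR)}")
    length = Decimal(int(end) - int(start) + 1)
    if unit == "bp":
        return float(length)
    scaled = length / Decimal(_UNIT_DIVISOR[unit])
    return float(scaled.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Annotation summaries
# ---------------------------------------------------------------------------

GFF_COLUMNS = (
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
)


def read_gff3(path) -> pd.DataFrame:
    """Genes from a GFF3 file; malformed lines are skipped with a warning."""
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                skipped += 1
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                skipped += 1
                continue
            rows.append(
                {
                    "seqid": fields[0],
                    "source": fields[1],
                    "type": fields[2],
                    "start": start,
                    "end": end,
                    "strand": fields[6],
                    "attributes": fields[8],
                }
            )
    if skipped:
        logger.warning("skipped %d malformed GFF3 lines in %s", skipped, path)
    return pd.DataFrame(
        rows, columns=["seqid", "source", "type", "start", "end", "strand", "attributes"]
    )


def summarize_region(
    region: CandidateRegion,
    table,
    gff: Optional[pd.DataFrame] = None,
    effective_impacts: Sequence[str] = ("HIGH", "MODERATE"),
) -> CandidateRegion:
    """Fill variant and gene counts for one region.

    ``table`` is a :class:`~bsaqtl.varfilter.BulkVariantTable` (or its
    frame); variants are counted when their position lies inside the closed
    interval, "effective" ones when their impact tag is in
    ``effective_impacts``.  A gene is counted when its span overlaps the
    region by >= 1 bp.
    """
    df = getattr(table, "df", table)
    inside = (
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] <= region.end)
    )
    sub = df[inside]
    is_snp = sub["variant_class"] == "SNP"
    is_eff = sub["impact"].isin(set(effective_impacts))
    genes = 0
    if gff is not None and len(gff):
        g = gff[gff["type"] == "gene"]
        genes = int(
            (
                (g["seqid"] == region.chrom)
                & (g["start"] <= region.end)
                & (g["end"] >= region.start)
            ).sum()
        )
    return replace(
        region,
        total_snps=int(is_snp.sum()),
        total_indels=int((~is_snp).sum()),
        effective_snps=int((is_snp & is_eff).sum()),
        effective_indels=int((~is_snp & is_eff).sum()),
        annotated_genes=genes,
    )


def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "length_bp": r.length,
                "methods": ",".join(sorted(r.methods)),
                "n_sites_above": r.n_sites_above,
                "total_snps": r.total_snps,
                "total_indels": r.total_indels,
                "effective_snps": r.effective_snps,
                "effective_indels": r.effective_indels,
                "annotated_genes": r.annotated_genes,
            }
            for r in regions
        ]
    )


def regions_to_bed(regions: Sequence[CandidateRegion], path) -> None:
    """BED export: 1-based closed -> 0-based half-open conversion."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(sorted(r.methods)) or "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")
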