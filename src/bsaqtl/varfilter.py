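"""Variant ingestion, quality filtering and parental polarization.

The central data structure is :class:`BulkVariantTable`, a thin wrapper
around a :class:`pandas.DataFrame` holding one row per variant site with
per-sample ref/alt allele depths for the four experimental roles
(``parent_dwarf``, ``parent_tall``, ``bulk_dwarf``, ``bulk_tall``).

Filtering retains biallelic sites with QUAL >= 30, MQ >= 30, per-parent
depth >= 10, per-bulk depth >= 15, no missing sample and opposite-homozygous
parents, attributing each removed site to the first failing rule in a fixed
order.  Polarization records which physical allele (REF or ALT) was carried
by the tall parent; all downstream allele frequencies refer to that allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the four experimental roles, in canonical column order
ROLES = ("parent_dwarf", "parent_tall", "bulk_dwarf", "bulk_tall")

#: default VCF sample name -> role mapping
DEFAULT_ROLE_MAP = {
    "P1": "parent_dwarf",
    "P2": "parent_tall",
    "BulkL": "bulk_dwarf",
    "BulkH": "bulk_tall",
}

DEPTH_COLUMNS = tuple(f"{role}_{a}" for role in ROLES for a in ("ref", "alt"))

SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "qual", "mq")

#: order in which filter rules claim a removed site
RULE_ORDER = (
    "biallelic",
    "qual",
    "mq",
    "parent_depth",
    "bulk_depth",
    "missing",
    "not_opposite",
)


@dataclass
class FilterThresholds:
    """Site-retention thresholds; defaults follow the standard BSA recipe."""

    min_qual: float = 30.0
    min_mq: float = 30.0
    min_parent_depth: int = 10
    min_bulk_depth: int = 15
    #: a parent counts as homozygous when its minor-allele read fraction
    #: does not exceed this tolerance
    max_parent_minor_fraction: float = 0.1


class BulkVariantTable:
    """Ordered table of biallelic variant sites with per-role allele depths.

    The underlying frame always carries :data:`SITE_COLUMNS`,
    :data:`DEPTH_COLUMNS`, ``variant_class``, ``impact`` and ``biallelic``;
    after :func:`polarize` it additionally carries ``tall_allele`` with
    values ``"ref"``/``"alt"``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in SITE_COLUMNS + DEPTH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        df = df.copy()
        if "variant_class" not in df.columns:
            snp = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
            df["variant_class"] = np.where(snp, "SNP", "InDel")
        if "impact" not in df.columns:
            df["impact"] = "MODIFIER"
        if "biallelic" not in df.columns:
            df["biallelic"] = True
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BulkVariantTable):
            return NotImplemented
        a = self.df[list(SITE_COLUMNS + DEPTH_COLUMNS)]
        b = other.df[list(SITE_COLUMNS + DEPTH_COLUMNS)]
        return a.shape == b.shape and bool((a.values == b.values).all())

    @property
    def is_polarized(self) -> bool:
        return "tall_allele" in self.df.columns

    def depth(self, role: str) -> pd.Series:
        return self.df[f"{role}_ref"] + self.df[f"{role}_alt"]

    def tall_counts(self, role: str) -> pd.Series:
        """Reads supporting the tall-parent allele in ``role``."""
        if not self.is_polarized:
            raise ValueError("table is not polarized")
        alt_is_tall = self.df["tall_allele"].to_numpy() == "alt"
        return pd.Series(
            np.where(
                alt_is_tall,
                self.df[f"{role}_alt"].to_numpy(),
                self.df[f"{role}_ref"].to_numpy(),
            ),
            index=self.df.index,
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BulkVariantTable":
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str}
        )
        if len(df) == 0:
            logger.warning("empty variant table read from %s", path)
        return cls(df)

    def to_vcf(self, path, contigs: Optional[Mapping[str, int]] = None) -> None:
        """Write a minimal VCF 4.2 with GT and AD per sample."""
        inv_roles = {v: k for k, v in DEFAULT_ROLE_MAP.items()}
        samples = [inv_roles[r] for r in ROLES]
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
            '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Annotation impact">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        ]
        if contigs is None:
            contigs = {
                c: int(g["pos"].max()) + 1000
                for c, g in self.df.groupby("chrom", sort=True)
            }
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
        )
        for row in self.df.itertuples(index=False):
            info = f"MQ={row.mq:g};IMPACT={row.impact}"
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                ".",
                str(row.ref),
                str(row.alt),
                f"{row.qual:g}",
                "PASS",
                info,
                "GT:AD",
            ]
            for role in ROLES:
                r = int(getattr(row, f"{role}_ref"))
                a = int(getattr(row, f"{role}_alt"))
                gt = _diploid_gt(r, a)
                fields.append(f"{gt}:{r},{a}")
            lines.append("\t".join(fields))
        Path(path).write_text("\n".join(lines) + "\n")


def _diploid_gt(ref_count: int, alt_count: int) -> str:
    total = ref_count + alt_count
    if total == 0:
        return "./."
    frac = alt_count / total
    if frac <= 0.2:
        return "0/0"
    if frac >= 0.8:
        return "1/1"
    return "0/1"


def read_variants(
    path,
    format: str = "vcf",
    role_map: Optional[Mapping[str, str]] = None,
) -> BulkVariantTable:
    """Load an unfiltered variant table from VCF (via cyvcf2) or TSV.

    Multi-allelic records are carried through with ``biallelic=False`` so the
    filter step can account for them.  A VCF record lacking AD for a mapped
    sample is a hard error naming that sample.
    """
    if format == "tsv":
        return BulkVariantTable.from_tsv(path)
    if format != "vcf":
        raise ValueError(f"unknown format: {format!r}")

    from cyvcf2 import VCF

    role_map = dict(DEFAULT_ROLE_MAP if role_map is None else role_map)
    unknown = set(role_map.values()) - set(ROLES)
    if unknown:
        raise ValueError(f"unknown sample roles in mapping: {sorted(unknown)}")

    vcf = VCF(str(path))
    sample_idx = {}
    for name, role in role_map.items():
        if name not in vcf.samples:
            raise ValueError(f"sample {name!r} not present in VCF {path}")
        sample_idx[role] = vcf.samples.index(name)
    missing_roles = set(ROLES) - set(sample_idx)
    if missing_roles:
        raise ValueError(f"no sample mapped to roles: {sorted(missing_roles)}")

    rows = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"missing AD field at {v.CHROM}:{v.POS} for samples {vcf.samples}"
            )
        mq = v.INFO.get("MQ")
        impact = v.INFO.get("IMPACT")
        row = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0] if v.ALT else ".",
            "qual": v.QUAL if v.QUAL is not None else float("nan"),
            "mq": float(mq) if mq is not None else float("nan"),
            "impact": impact if impact is not None else "MODIFIER",
            "biallelic": len(v.ALT) == 1,
        }
        for role, idx in sample_idx.items():
            ref_c = int(ad[idx][0])
            alt_c = int(ad[idx][1]) if ad.shape[1] > 1 else 0
            row[f"{role}_ref"] = max(ref_c, 0)
            row[f"{role}_alt"] = max(alt_c, 0)
        rows.append(row)
    if not rows:
        logger.warning("empty VCF read from %s", path)
        rows = []
        df = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in _empty_schema().items()}
        )
        return BulkVariantTable(df)
    return BulkVariantTable(pd.DataFrame(rows))


def _empty_schema():
    schema = {
        "chrom": str,
        "pos": np.int64,
        "ref": str,
        "alt": str,
        "qual": float,
        "mq": float,
        "impact": str,
        "biallelic": bool,
    }
    for col in DEPTH_COLUMNS:
        schema[col] = np.int64
    return schema


def _parent_major(df: pd.DataFrame, role: str) -> np.ndarray:
    """Per-site major allele of a parent: 'ref', 'alt', or '?' on ties."""
    r = df[f"{role}_ref"].to_numpy(dtype=float)
    a = df[f"{role}_alt"].to_numpy(dtype=float)
    out = np.where(r > a, "ref", np.where(a > r, "alt", "?"))
    return out


def _parent_is_homozygous(df: pd.DataFrame, role: str, tol: float) -> np.ndarray:
    r = df[f"{role}_ref"].to_numpy(dtype=float)
    a = df[f"{role}_alt"].to_numpy(dtype=float)
    total = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(r, a) / np.where(total > 0, total, np.nan)
    return (total > 0) & (minor <= tol)


def apply_filters(
    table: BulkVariantTable,
    thresholds: Optional[FilterThresholds] = None,
) -> tuple[BulkVariantTable, dict]:
    """Apply the retention rules; return (filtered table, removal report).

    Each removed site is attributed to the *first* failing rule in
    :data:`RULE_ORDER`, so report counts sum to input - output.
    """
    t = FilterThresholds() if thresholds is None else thresholds
    df = table.df

    parent_depths = [table.depth(r) for r in ("parent_dwarf", "parent_tall")]
    bulk_depths = [table.depth(r) for r in ("bulk_dwarf", "bulk_tall")]
    hom_d = _parent_is_homozygous(df, "parent_dwarf", t.max_parent_minor_fraction)
    hom_t = _parent_is_homozygous(df, "parent_tall", t.max_parent_minor_fraction)
    major_d = _parent_major(df, "parent_dwarf")
    major_t = _parent_major(df, "parent_tall")

    passes = {
        "biallelic": df["biallelic"].to_numpy(dtype=bool),
        "qual": df["qual"].to_numpy(dtype=float) >= t.min_qual,
        "mq": df["mq"].to_numpy(dtype=float) >= t.min_mq,
        "parent_depth": np.logical_and(
            parent_depths[0].to_numpy() >= t.min_parent_depth,
            parent_depths[1].to_numpy() >= t.min_parent_depth,
        ),
        "bulk_depth": np.logical_and(
            bulk_depths[0].to_numpy() >= t.min_bulk_depth,
            bulk_depths[1].to_numpy() >= t.min_bulk_depth,
        ),
        "missing": np.all(
            [table.depth(r).to_numpy() > 0 for r in ROLES], axis=0
        ),
        "not_opposite": hom_d & hom_t & (major_d != major_t)
        & (major_d != "?") & (major_t != "?"),
    }

    keep = np.ones(len(df), dtype=bool)
    removed = {}
    for rule in RULE_ORDER:
        fails_here = keep & ~passes[rule]
        removed[rule] = int(fails_here.sum())
        keep &= passes[rule]

    report = {
        "input_sites": int(len(df)),
        "retained_sites": int(keep.sum()),
        "removed": removed,
        "thresholds": {
            "min_qual": t.min_qual,
            "min_mq": t.min_mq,
            "min_parent_depth": t.min_parent_depth,
            "min_bulk_depth": t.min_bulk_depth,
            "max_parent_minor_fraction": t.max_parent_minor_fraction,
        },
    }
    return BulkVariantTable(df[keep].reset_index(drop=True)), report


def polarize(
    table: BulkVariantTable, tol: float = 0.1
) -> BulkVariantTable:
    """Record, per site, which allele the tall parent carries.

    Requires opposite-homozygous parents at every site (guaranteed after
    :func:`apply_filters`); an ambiguous site raises ``ValueError``.
    """
    df = table.df.copy()
    hom_d = _parent_is_homozygous(df, "parent_dwarf", tol)
    hom_t = _parent_is_homozygous(df, "parent_tall", tol)
    major_d = _parent_major(df, "parent_dwarf")
    major_t = _parent_major(df, "parent_tall")
    ok = hom_d & hom_t & (major_d != major_t) & (major_t != "?") & (major_d != "?")
    if not ok.all():
        bad = df.loc[~ok, ["chrom", "pos"]].head(5).to_records(index=False)
        raise ValueError(
            f"ambiguous parental genotype at {int((~ok).sum())} sites, "
            f"e.g. {list(bad)}"
        )
    df["tall_allele"] = major_t
    return BulkVariantTable(df)
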