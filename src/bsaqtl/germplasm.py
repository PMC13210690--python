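"""Haplotype-phenotype association in a germplasm panel, plus qPCR contrast.

Accessions carry an allele string over a small set of panel sites, market
class and region labels, and one height measurement per year.  The module
partitions accessions into haplotype groups, compares group heights by
one-way ANOVA followed by Duncan's multiple range test (compact letter
display), tests individual sites by two-sample t-test, tabulates haplotype
frequencies by market class or geography, and computes 2^-ddCt relative
expression from qPCR Ct tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MISSING_ALLELES = set("-.nN?")


@dataclass
class HaplotypeGroup:
    label: str
    alleles: str
    members: list
    mean_by_year: dict  # year -> mean height
    overall_mean: float

    @property
    def n(self) -> int:
        return len(self.members)


def _height_columns(panel: pd.DataFrame) -> list[str]:
    cols = [c for c in panel.columns if c.startswith("height_")]
    if not cols:
        raise ValueError("panel has no height_<year> columns")
    return cols


def define_haplotypes(panel: pd.DataFrame) -> list[HaplotypeGroup]:
    """Partition accessions by exact allele string.

    Accessions with incomplete strings (any character in '-.nN?') are
    excluded with a log entry.  Groups are labelled Hap1..HapK in order of
    descending overall (all-years) mean height, ties broken by lexicographic
    allele string.
    """
    if len(panel) == 0:
        raise ValueError("empty accession panel")
    hcols = _height_columns(panel)
    complete = ~panel["alleles"].map(
        lambda s: any(ch in MISSING_ALLELES for ch in str(s))
    )
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("excluded %d accessions with incomplete allele strings", n_excluded)
    panel = panel[complete]

    groups = []
    for alleles, sub in panel.groupby("alleles", sort=True):
        mean_by_year = {
            int(c.split("_", 1)[1]): float(sub[c].mean()) for c in hcols
        }
        groups.append(
            HaplotypeGroup(
                label="",
                alleles=str(alleles),
                members=list(sub["accession"]),
                mean_by_year=mean_by_year,
                overall_mean=float(sub[hcols].to_numpy().mean()),
            )
        )
    groups.sort(key=lambda g: (-g.overall_mean, g.alleles))
    for i, g in enumerate(groups):
        g.label = f"Hap{i + 1}"
    return groups


def assignments(groups: Sequence[HaplotypeGroup]) -> dict:
    """accession id -> haplotype label."""
    return {m: g.label for g in groups for m in g.members}


# ---------------------------------------------------------------------------
# One-way ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class DuncanResult:
    f_stat: float
    p_value: float
    df_between: int
    df_error: int
    ms_error: float
    means: dict  # label -> mean, in descending order
    sizes: dict
    letters: dict  # label -> compact letter string
    critical_ranges: dict  # p (number of means spanned) -> least significant range
    excluded: list  # labels excluded (group size < 2)
    alpha: float = 0.05


def duncan_critical_range(
    p: int, df_error: int, ms_error: float, n_harmonic: float, alpha: float = 0.05
) -> float:
    """Least significant range for means ``p`` ranks apart.

    Uses the studentized-range quantile at Duncan's protection level
    ``alpha_p = 1 - (1 - alpha)**(p - 1)``, scaled by sqrt(MS_error / n_h).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    q = sps.studentized_range.ppf(1.0 - alpha_p, p, df_error)
    return float(q * np.sqrt(ms_error / n_harmonic))


def _compact_letters(order: list, nonsig: set) -> dict:
    """Letter display from declared non-significant index ranges.

    ``nonsig`` holds inclusive (i, j) index ranges (on the descending-mean
    order) declared homogeneous; maximal ranges each get a letter, and any
    index not covered gets its own letter.
    """
    k = len(order)
    maximal = [
        (i, j)
        for (i, j) in nonsig
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in nonsig)
    ]
    for i in range(k):
        if not any(a <= i <= b for (a, b) in nonsig):
            maximal.append((i, i))
    maximal.sort()
    letters = {label: "" for label in order}
    for letter, (a, b) in zip(_letter_stream(), maximal):
        for i in range(a, b + 1):
            letters[order[i]] += letter
    return letters


def _letter_stream():
    for size in itertools.count(1):
        for combo in itertools.product("abcdefghijklmnopqrstuvwxyz", repeat=size):
            yield "".join(combo)


def anova_duncan(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> DuncanResult:
    """One-way ANOVA followed by Duncan's multiple range test.

    Groups of size 1 are excluded from the letter display (they contribute
    no within-group variance) and reported in ``excluded``.  The stepwise
    procedure tests ranges widest-first; a range wholly inside an already
    declared homogeneous range is accepted without testing (standard
    protection rule), and compact letters are assigned so groups sharing a
    letter never differ significantly.
    """
    data = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    excluded = [k for k, v in data.items() if len(v) < 2]
    data = {k: v for k, v in data.items() if len(v) >= 2}
    if len(data) < 2:
        raise ValueError("need at least two groups of size >= 2")

    groups = list(data.values())
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df_between = k - 1
    df_error = n_total - k
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_error = ss_within / df_error
    if ms_error > 0:
        f_stat = (ss_between / df_between) / ms_error
        p_value = float(sps.f.sf(f_stat, df_between, df_error))
    else:
        f_stat = float("inf") if ss_between > 0 else 0.0
        p_value = 0.0 if ss_between > 0 else 1.0

    order = sorted(data, key=lambda lab: -data[lab].mean())
    means = {lab: float(data[lab].mean()) for lab in order}
    sizes = {lab: int(len(data[lab])) for lab in order}
    n_h = k / sum(1.0 / sizes[lab] for lab in order)

    critical = {
        p: duncan_critical_range(p, df_error, ms_error, n_h, alpha)
        for p in range(2, k + 1)
    }

    nonsig: set[tuple[int, int]] = set()
    if ms_error == 0:
        # degenerate: zero within-group variance; any difference separates
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                if means[order[i]] == means[order[j]]:
                    nonsig.add((i, j))
    else:
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                if any(a <= i and j <= b for (a, b) in nonsig):
                    continue
                diff = means[order[i]] - means[order[j]]
                if diff <= critical[span]:
                    nonsig.add((i, j))

    letters = _compact_letters(order, nonsig)
    return DuncanResult(
        f_stat=float(f_stat),
        p_value=p_value,
        df_between=df_between,
        df_error=df_error,
        ms_error=float(ms_error),
        means=means,
        sizes=sizes,
        letters=letters,
        critical_ranges=critical,
        excluded=excluded,
        alpha=alpha,
    )


def group_heights(
    panel: pd.DataFrame,
    groups: Sequence[HaplotypeGroup],
    year: Optional[int] = None,
) -> dict:
    """label -> height values, for one year or the per-accession year mean."""
    hcols = _height_columns(panel)
    col = f"height_{year}" if year is not None else None
    if col is not None and col not in panel.columns:
        raise ValueError(f"panel lacks column {col}")
    indexed = panel.set_index("accession")
    out = {}
    for g in groups:
        sub = indexed.loc[g.members]
        out[g.label] = (
            sub[col].to_numpy(float)
            if col is not None
            else sub[hcols].to_numpy(float).mean(axis=1)
        )
    return out


# ---------------------------------------------------------------------------
# Single-marker tests
# ---------------------------------------------------------------------------

@dataclass
class SiteTestResult:
    status: str  # "ok" | "monomorphic" | "degenerate"
    site_index: int
    year: Optional[int]
    allele_a: Optional[str] = None
    allele_b: Optional[str] = None
    n_a: int = 0
    n_b: int = 0
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    t: float = float("nan")
    df: int = 0
    p: float = float("nan")


def single_marker_test(
    panel: pd.DataFrame,
    site_index: int,
    year: Optional[int] = None,
    equal_var: bool = True,
) -> SiteTestResult:
    """Two-sample t-test of height between the two allele classes at a site."""
    alleles = panel["alleles"].str[site_index]
    present = ~alleles.isin(MISSING_ALLELES)
    sub = panel[present]
    alleles = alleles[present]
    observed = sorted(alleles.unique())
    if len(observed) != 2:
        return SiteTestResult(status="monomorphic", site_index=site_index, year=year)

    if year is not None:
        heights = sub[f"height_{year}"].to_numpy(float)
    else:
        heights = sub[_height_columns(sub)].to_numpy(float).mean(axis=1)
    a, b = observed
    xa = heights[(alleles == a).to_numpy()]
    xb = heights[(alleles == b).to_numpy()]
    base = SiteTestResult(
        status="ok",
        site_index=site_index,
        year=year,
        allele_a=a,
        allele_b=b,
        n_a=len(xa),
        n_b=len(xb),
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        df=len(xa) + len(xb) - 2,
    )
    if xa.std(ddof=1 if len(xa) > 1 else 0) == 0 and xb.std(
        ddof=1 if len(xb) > 1 else 0
    ) == 0:
        base.status = "degenerate"
        return base
    t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
    base.t, base.p = float(t), float(p)
    return base


# ---------------------------------------------------------------------------
# Frequency breakdowns
# ---------------------------------------------------------------------------

def frequency_breakdown(
    panel: pd.DataFrame,
    groups: Sequence[HaplotypeGroup],
    by: str = "market_class",
) -> pd.DataFrame:
    """Haplotype percentages per stratum (rows), to 1 decimal.

    Percentages within a stratum sum to exactly 100.0: cells are rounded to
    one decimal and any rounding remainder is assigned to the stratum's
    largest cell.  Empty strata are excluded with a warning.
    """
    if by not in panel.columns:
        raise ValueError(f"panel lacks stratification column {by!r}")
    label_of = assignments(groups)
    sub = panel[panel["accession"].isin(label_of)].copy()
    sub["haplotype"] = sub["accession"].map(label_of)
    hap_order = [g.label for g in groups]

    rows = {}
    for stratum, s in sub.groupby(by, sort=True):
        if len(s) == 0:
            logger.warning("empty stratum %r excluded", stratum)
            continue
        counts = s["haplotype"].value_counts()
        raw = np.array([100.0 * counts.get(h, 0) / len(s) for h in hap_order])
        pct = np.round(raw, 1)
        largest = int(np.argmax(raw))
        pct[largest] = np.round(pct[largest] + (100.0 - pct.sum()), 1)
        rows[stratum] = pct
    return pd.DataFrame.from_dict(rows, orient="index", columns=hap_order)


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

@dataclass
class DdctResult:
    per_replicate: pd.DataFrame  # group, gene, bio_rep, dct, ddct, rel_expr
    summary: pd.DataFrame  # per (gene, group): mean rel expr, fold, t, p
    reference_group: str


def ddct(
    samples: pd.DataFrame,
    reference_group: str,
    group_col: str = "line",
) -> DdctResult:
    """Relative expression by the 2^-ddCt method with a per-gene t-test.

    Technical replicates are averaged within each biological replicate
    first; dCt = Ct_target - Ct_reference per biological replicate; ddCt is
    taken against the reference group's mean dCt per gene.  Replicates
    missing either Ct are excluded with a log entry.  The group contrast is
    a two-sample t-test on dCt values against the reference group.
    """
    required = {group_col, "gene", "bio_rep", "ct_target", "ct_reference"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
    df = samples.copy()
    bad = df["ct_target"].isna() | df["ct_reference"].isna()
    if bad.any():
        logger.info("excluded %d qPCR rows with missing Ct", int(bad.sum()))
        df = df[~bad]
    if reference_group not in set(df[group_col]):
        raise ValueError(f"reference group {reference_group!r} absent from table")

    bio = (
        df.groupby([group_col, "gene", "bio_rep"], sort=True)[
            ["ct_target", "ct_reference"]
        ]
        .mean()
        .reset_index()
    )
    bio["dct"] = bio["ct_target"] - bio["ct_reference"]

    ref_mean = (
        bio[bio[group_col] == reference_group].groupby("gene")["dct"].mean()
    )
    bio["ddct"] = bio["dct"] - bio["gene"].map(ref_mean)
    bio["rel_expr"] = 2.0 ** (-bio["ddct"])

    rows = []
    for (gene, group), s in bio.groupby(["gene", group_col], sort=True):
        ref = bio[(bio["gene"] == gene) & (bio[group_col] == reference_group)]
        t = p = float("nan")
        if (
            group != reference_group
            and len(s) >= 2
            and len(ref) >= 2
            and (s["dct"].std(ddof=1) > 0 or ref["dct"].std(ddof=1) > 0)
        ):
            t, p = sps.ttest_ind(s["dct"], ref["dct"], equal_var=True)
        rows.append(
            {
                "gene": gene,
                group_col: group,
                "n_bio": len(s),
                "mean_rel_expr": float(s["rel_expr"].mean()),
                "fold_change": float(2.0 ** (-s["ddct"].mean())),
                "t": float(t),
                "p": float(p),
            }
        )
    bio = bio.rename(columns={group_col: "group"})
    return DdctResult(
        per_replicate=bio,
        summary=pd.DataFrame(rows),
        reference_group=reference_group,
    )
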