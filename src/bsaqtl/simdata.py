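"""Synthetic bulk-segregant experiment generator.

Simulates an F2 population derived from two fully inbred, opposite-homozygous
parents segregating a single major QTL, applies two-tail truncation selection
to form phenotypic bulks, and samples short-read allele depths for the two
parents and the two bulks.  Also provides small fixture generators for the
fine-mapping and germplasm-panel modules so that every downstream stage can be
exercised without external data.

Model summary
-------------
* Meiosis: crossover count per gamete ~ Poisson(genetic length in Morgans),
  crossover positions uniform on the map (constant cM/Mb), no interference.
* Trait: ``height = mu + a*(g-1) + d*[g==1] + N(0, sigma^2)`` where ``g`` is
  the number of tall-parent alleles at the QTL (term dropped when no QTL).
* Reads: per site and sample, depth ~ Poisson(mean_depth); tall-allele read
  count ~ Binomial(depth, f*(1-eps) + (1-f)*eps) with ``f`` the true
  tall-allele frequency in that sample and ``eps`` a symmetric base error.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config, so every output is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .varfilter import (
    ROLES,
    BulkVariantTable,
    DEPTH_COLUMNS,
)

_BASES = np.array(["A", "C", "G", "T"])

#: impact labels emitted by the read sampler, with sampling probabilities
IMPACT_LABELS = ("MODIFIER", "LOW", "MODERATE", "HIGH")
IMPACT_PROBS = (0.82, 0.08, 0.08, 0.02)

#: fraction of simulated sites emitted as 1-bp insertions instead of SNPs
INDEL_FRACTION = 0.1


@dataclass
class SimConfig:
    """Parameters of one simulated F2 bulk-segregant experiment."""

    seed: int
    n_individuals: int = 715
    bulk_size: int = 30
    n_sites: int = 2000
    chrom_length: int = 150_000_000
    chrom_name: str = "chr1"
    cm_per_mb: float = 1.0
    qtl_position: Optional[int] = None
    additive_effect: float = 0.0
    dominance_effect: float = 0.0
    residual_sd: float = 10.0
    mean_height: float = 180.0
    mean_depth: float = 27.0
    base_error: float = 0.001

    def __post_init__(self) -> None:
        if 2 * self.bulk_size > self.n_individuals:
            raise ValueError("2*bulk_size must not exceed n_individuals")
        if not (0.0 <= self.base_error < 0.5):
            raise ValueError("base_error must lie in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.chrom_length < self.n_sites:
            raise ValueError("chrom_length must accommodate n_sites positions")
        if self.qtl_position is not None and not (
            1 <= self.qtl_position <= self.chrom_length
        ):
            raise ValueError("qtl_position must lie within [1, chrom_length]")

    @property
    def genetic_length_morgans(self) -> float:
        """Chromosome length on the genetic map, in Morgans."""
        return self.chrom_length / 1e6 * self.cm_per_mb / 100.0

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulated population (for recovery tests)."""

    config: SimConfig
    positions: np.ndarray  # (n_sites,) 1-based bp, strictly increasing
    genotypes: np.ndarray  # (n_individuals, n_sites) copies of tall allele
    qtl_genotypes: Optional[np.ndarray]  # (n_individuals,) or None
    phenotypes: np.ndarray  # (n_individuals,) cm
    dwarf_bulk: Optional[np.ndarray] = None  # individual indices, sorted
    tall_bulk: Optional[np.ndarray] = None
    freq_dwarf: Optional[np.ndarray] = None  # true tall-allele freq per site
    freq_tall: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.genotypes.min() < 0 or self.genotypes.max() > 2:
            raise ValueError("genotypes must be allele copy counts in {0,1,2}")


def _site_positions(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Sorted unique 1-based positions; one site pinned at the QTL if set."""
    pos = set()
    while len(pos) < config.n_sites:
        need = config.n_sites - len(pos)
        pos.update(rng.integers(1, config.chrom_length + 1, size=2 * need).tolist())
    arr = np.sort(np.fromiter(pos, dtype=np.int64, count=len(pos)))
    if len(arr) > config.n_sites:
        arr = rng.choice(arr, size=config.n_sites, replace=False)
    positions = np.sort(arr)
    if config.qtl_position is not None and config.qtl_position not in pos:
        # replace the nearest simulated site with the QTL position itself
        i = int(np.argmin(np.abs(positions - config.qtl_position)))
        positions[i] = config.qtl_position
        positions = np.unique(positions)
    return positions


def _gamete(
    rng: np.random.Generator, config: SimConfig, query: np.ndarray
) -> np.ndarray:
    """Alleles (0/1) transmitted by one F1 gamete at ``query`` positions."""
    n_xo = rng.poisson(config.genetic_length_morgans)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return np.full(query.shape, start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0.0, config.chrom_length, size=n_xo))
    crossings = np.searchsorted(breaks, query.astype(np.float64))
    return ((start + crossings) % 2).astype(np.int8)


def simulate_f2(config: SimConfig) -> SimTruth:
    """Simulate an F2 population with genotypes and phenotypes.

    Each individual receives two independent F1 gametes; the genotype at a
    site is the number of tall-parent alleles (0/1/2).  Deterministic for a
    given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0x51])
    positions = _site_positions(rng, config)
    n = config.n_individuals

    has_qtl = config.qtl_position is not None
    if has_qtl:
        query = np.append(positions, config.qtl_position)
    else:
        query = positions

    genotypes = np.empty((n, len(positions)), dtype=np.int8)
    qtl_g = np.empty(n, dtype=np.int8) if has_qtl else None
    for i in range(n):
        g = _gamete(rng, config, query) + _gamete(rng, config, query)
        if has_qtl:
            genotypes[i] = g[:-1]
            qtl_g[i] = g[-1]
        else:
            genotypes[i] = g

    noise = rng.normal(0.0, config.residual_sd, size=n)
    phenotypes = config.mean_height + noise
    if has_qtl:
        phenotypes = (
            phenotypes
            + config.additive_effect * (qtl_g.astype(float) - 1.0)
            + config.dominance_effect * (qtl_g == 1)
        )
    return SimTruth(
        config=config,
        positions=positions,
        genotypes=genotypes,
        qtl_genotypes=qtl_g,
        phenotypes=phenotypes,
    )


def select_bulks(truth: SimTruth, bulk_size: Optional[int] = None) -> SimTruth:
    """Two-tail truncation selection into dwarf and tall bulks.

    The dwarf bulk holds the ``bulk_size`` lowest phenotypes, the tall bulk
    the ``bulk_size`` highest.  Ties are broken by individual index (stable
    sort), so selection is reproducible.  True tall-allele frequencies per
    bulk are recomputed from the genotypes.
    """
    bulk_size = truth.config.bulk_size if bulk_size is None else bulk_size
    n = len(truth.phenotypes)
    if 2 * bulk_size > n:
        raise ValueError("2*bulk_size exceeds the population size")
    order = np.argsort(truth.phenotypes, kind="stable")
    dwarf = np.sort(order[:bulk_size])
    tall = np.sort(order[n - bulk_size:])
    freq_d = truth.genotypes[dwarf].sum(axis=0) / (2.0 * bulk_size)
    freq_t = truth.genotypes[tall].sum(axis=0) / (2.0 * bulk_size)
    return dataclasses.replace(
        truth, dwarf_bulk=dwarf, tall_bulk=tall, freq_dwarf=freq_d, freq_tall=freq_t
    )


def _sample_counts(
    rng: np.random.Generator, freq: np.ndarray, lam: float, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """(tall-allele reads, other reads) for one sample across sites."""
    depth = rng.poisson(lam, size=len(freq))
    p = freq * (1.0 - eps) + (1.0 - freq) * eps
    tall = rng.binomial(depth, p)
    return tall, depth - tall


def sample_reads(truth: SimTruth, config: Optional[SimConfig] = None) -> BulkVariantTable:
    """Sample per-sample allele depths and emit an unfiltered variant table.

    Parents are emitted as opposite homozygotes (dwarf parent carries none of
    the tall allele, tall parent all of it) subject to the base error; bulks
    use the true bulk frequencies.  Which physical allele (REF or ALT) is the
    tall-parent allele is randomized per site so polarization is exercised
    downstream.  QUAL and MQ are filled with passing defaults (60).
    """
    config = truth.config if config is None else config
    if truth.freq_dwarf is None or truth.freq_tall is None:
        raise ValueError("bulks must be selected before sampling reads")
    rng = np.random.default_rng([config.seed, 0x5EAD])
    m = len(truth.positions)
    lam, eps = config.mean_depth, config.base_error

    zeros = np.zeros(m)
    ones = np.ones(m)
    counts = {
        "parent_dwarf": _sample_counts(rng, zeros, lam, eps),
        "parent_tall": _sample_counts(rng, ones, lam, eps),
        "bulk_dwarf": _sample_counts(rng, truth.freq_dwarf, lam, eps),
        "bulk_tall": _sample_counts(rng, truth.freq_tall, lam, eps),
    }

    tall_is_alt = rng.random(m) < 0.5
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)
    is_indel = rng.random(m) < INDEL_FRACTION
    ins = _BASES[rng.integers(0, 4, size=m)]
    alt = np.where(is_indel, np.char.add(alt.astype(str), ins), alt).astype(object)

    data = {
        "chrom": config.chrom_name,
        "pos": truth.positions,
        "ref": ref,
        "alt": alt,
        "qual": np.full(m, 60.0),
        "mq": np.full(m, 60.0),
        "impact": rng.choice(IMPACT_LABELS, size=m, p=IMPACT_PROBS),
        "biallelic": True,
    }
    for role in ROLES:
        tall, other = counts[role]
        data[f"{role}_ref"] = np.where(tall_is_alt, other, tall)
        data[f"{role}_alt"] = np.where(tall_is_alt, tall, other)
    df = pd.DataFrame(data)
    df["variant_class"] = np.where(is_indel, "InDel", "SNP")
    for col in DEPTH_COLUMNS:
        df[col] = df[col].astype(np.int64)
    return BulkVariantTable(df)


def simulate_experiment(config: SimConfig) -> tuple[SimTruth, BulkVariantTable]:
    """Convenience wrapper: simulate, select bulks, sample reads."""
    truth = select_bulks(simulate_f2(config))
    return truth, sample_reads(truth, config)


# ---------------------------------------------------------------------------
# Fine-mapping fixtures
# ---------------------------------------------------------------------------

def make_finemap_fixture(
    seed: int,
    n_markers: int,
    qtl_marker_index: int,
    n_recombinants: int,
    chrom: str = "chr1",
    start_bp: int = 1_000_000,
    spacing_bp: int = 100_000,
):
    """Generate an ordered marker panel plus recombinant profiles.

    Recombinants carry one or two breakpoints between parental marker states
    and a phenotype class consistent with a dominant tall allele at the
    marker at ``qtl_marker_index``; substitution mapping of the returned
    profiles therefore always brackets that marker.

    Returns ``(markers, profiles)`` where ``markers`` is a list of
    ``(marker_id, chrom, pos)`` tuples and ``profiles`` a list of
    :class:`bsaqtl.finemap.RecombinantProfile`.
    """
    from .finemap import InheritanceModel, RecombinantProfile

    if not 0 <= qtl_marker_index < n_markers:
        raise ValueError("qtl_marker_index out of range")
    rng = np.random.default_rng([seed, 0xF1])
    markers = [
        (f"M{i + 1}", chrom, start_bp + i * spacing_bp) for i in range(n_markers)
    ]
    model = InheritanceModel(het_phenotype="tall")
    states = np.array(["A", "H", "B"])
    profiles = []
    for i in range(n_recombinants):
        n_breaks = 1 if n_markers < 3 or rng.random() < 0.7 else 2
        cuts = np.sort(rng.choice(np.arange(1, n_markers), size=n_breaks, replace=False))
        segs = np.split(np.arange(n_markers), cuts)
        calls = np.empty(n_markers, dtype=object)
        prev = None
        for seg in segs:
            choices = [s for s in states if s != prev]
            prev = rng.choice(choices)
            calls[seg] = prev
        phenotype = model.predict(calls[qtl_marker_index])
        profiles.append(
            RecombinantProfile(
                individual=f"R{i + 1}",
                generation="F2",
                calls=list(calls),
                phenotype=phenotype,
            )
        )
    return markers, profiles


# ---------------------------------------------------------------------------
# Germplasm-panel fixtures
# ---------------------------------------------------------------------------

MARKET_CLASSES = ("oilseed", "confection")
REGIONS_POOL = ("Asia", "Europe", "North America", "South America")


def _default_allele_strings(k: int, n_sites: int) -> list[str]:
    """First ``k`` distinct allele strings over {A,C,G,T}^n_sites."""
    if k > 4**n_sites:
        raise ValueError("more groups than possible allele strings")
    out = []
    for i in range(k):
        s, x = [], i
        for _ in range(n_sites):
            s.append("ACGT"[x % 4])
            x //= 4
        out.append("".join(s))
    return out


def make_panel_fixture(
    seed: int,
    group_sizes: Sequence[int],
    group_means: Sequence[float],
    sd: float,
    n_sites: int = 4,
    years: Sequence[int] = (2024, 2025),
    allele_strings: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Generate an accession panel with known haplotype-group structure.

    Each group gets a distinct allele string across ``n_sites`` panel sites;
    heights for every listed year are drawn ``Normal(group_mean, sd**2)``;
    market class and region labels are assigned round-robin.
    """
    if len(group_sizes) != len(group_means):
        raise ValueError("group_sizes and group_means must have equal length")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    k = len(group_sizes)
    if allele_strings is None:
        allele_strings = _default_allele_strings(k, n_sites)
    else:
        allele_strings = [str(s) for s in allele_strings]
        if len(allele_strings) != k:
            raise ValueError("one allele string required per group")
        if len(set(allele_strings)) != k:
            raise ValueError("allele strings must be distinct per group")
        if any(len(s) != n_sites for s in allele_strings):
            raise ValueError(f"allele strings must have length {n_sites}")

    rng = np.random.default_rng([seed, 0xAC])
    rows = []
    acc = 0
    for g, (size, mean) in enumerate(zip(group_sizes, group_means)):
        for _ in range(size):
            row = {
                "accession": f"ACC{acc + 1:04d}",
                "alleles": allele_strings[g],
                "market_class": MARKET_CLASSES[acc % len(MARKET_CLASSES)],
                "region": REGIONS_POOL[acc % len(REGIONS_POOL)],
            }
            for year in years:
                row[f"height_{year}"] = mean + rng.normal(0.0, sd)
            rows.append(row)
            acc += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR fixtures
# ---------------------------------------------------------------------------

def make_qpcr_fixture(
    seed: int,
    genes: Sequence[str] = ("gene1",),
    lines: Sequence[str] = ("dwarf", "tall"),
    log2_fold: float = 2.0,
    n_bio: int = 3,
    n_tech: int = 3,
    ct_reference: float = 20.0,
    ct_sd: float = 0.1,
) -> pd.DataFrame:
    """Ct table for a two-line expression contrast.

    The second line's target Ct is shifted down by ``log2_fold`` cycles
    relative to the first (higher expression).
    """
    rng = np.random.default_rng([seed, 0xC7])
    rows = []
    for gene in genes:
        for li, line in enumerate(lines):
            base_target = 25.0 - (log2_fold if li > 0 else 0.0)
            for b in range(n_bio):
                for t in range(n_tech):
                    rows.append(
                        {
                            "line": line,
                            "gene": gene,
                            "bio_rep": b + 1,
                            "tech_rep": t + 1,
                            "ct_target": base_target + rng.normal(0.0, ct_sd),
                            "ct_reference": ct_reference + rng.normal(0.0, ct_sd),
                        }
                    )
    return pd.DataFrame(rows)
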