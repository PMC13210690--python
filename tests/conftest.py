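import numpy as np
import pandas as pd
import pytest

from bsaqtl.varfilter import BulkVariantTable, ROLES


def make_table(rows, polarized=False):
    """Build a BulkVariantTable from compact per-site dicts.

    Each row dict may give: pos, qual, mq, chrom, ref, alt, impact,
    biallelic, and per-role (ref, alt) depth tuples under the role name.
    Unspecified fields get passing defaults (opposite-homozygous parents,
    balanced bulks).
    """
    defaults = {
        "parent_dwarf": (30, 0),
        "parent_tall": (0, 30),
        "bulk_dwarf": (15, 15),
        "bulk_tall": (15, 15),
    }
    out = []
    for i, row in enumerate(rows):
        rec = {
            "chrom": row.get("chrom", "chr1"),
            "pos": row.get("pos", (i + 1) * 1000),
            "ref": row.get("ref", "A"),
            "alt": row.get("alt", "T"),
            "qual": row.get("qual", 60.0),
            "mq": row.get("mq", 60.0),
            "impact": row.get("impact", "MODIFIER"),
            "biallelic": row.get("biallelic", True),
        }
        for role in ROLES:
            r, a = row.get(role, defaults[role])
            rec[f"{role}_ref"] = r
            rec[f"{role}_alt"] = a
        out.append(rec)
    table = BulkVariantTable(pd.DataFrame(out))
    if polarized:
        from bsaqtl.varfilter import polarize

        table = polarize(table)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_experiment():
    """A modest simulated experiment with a strong QTL, reused across tests."""
    from bsaqtl.simdata import SimConfig, simulate_experiment

    cfg = SimConfig(
        seed=77,
        n_individuals=300,
        bulk_size=30,
        n_sites=400,
        chrom_length=60_000_000,
        qtl_position=30_000_000,
        additive_effect=30.0,
        residual_sd=10.0,
        mean_depth=27.0,
    )
    truth, table = simulate_experiment(cfg)
    return cfg, truth, table
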