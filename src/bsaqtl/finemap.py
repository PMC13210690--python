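"""Substitution mapping from recombinant marker genotypes.

Each recombinant individual carries an ordered vector of codominant marker
calls (``A`` = dwarf-parent homozygote, ``H`` = heterozygote, ``B`` =
tall-parent homozygote, ``-`` = missing) and a phenotype class.  Under a
declared inheritance model the QTL can only reside at markers whose call
predicts the observed phenotype; intersecting those consistent marker sets
across recombinants narrows the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CALLS = ("A", "H", "B", "-")
PHENOTYPES = ("dwarf", "tall")


@dataclass(frozen=True)
class InheritanceModel:
    """Phenotype predicted by each marker call at the causal locus.

    ``A`` always predicts dwarf and ``B`` tall; the heterozygote prediction
    encodes dominance (``het_phenotype="tall"`` = dominant tall allele).
    """

    het_phenotype: str = "tall"

    def __post_init__(self) -> None:
        if self.het_phenotype not in PHENOTYPES:
            raise ValueError("het_phenotype must be 'dwarf' or 'tall'")

    def predict(self, call: str) -> Optional[str]:
        if call == "A":
            return "dwarf"
        if call == "B":
            return "tall"
        if call == "H":
            return self.het_phenotype
        if call == "-":
            return None
        raise ValueError(f"unknown marker call {call!r}")


@dataclass
class RecombinantProfile:
    """Ordered marker calls plus phenotype class for one individual."""

    individual: str
    calls: list
    phenotype: str
    generation: str = "F2"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError("phenotype must be 'dwarf' or 'tall'")
        bad = [c for c in self.calls if c not in CALLS]
        if bad:
            raise ValueError(f"unknown marker calls: {bad}")


@dataclass
class MappingResult:
    """Outcome of substitution mapping over a recombinant set."""

    status: str  # "ok" | "no_consistent_placement"
    left_bp: Optional[int]
    right_bp: Optional[int]
    consistent_indices: frozenset  # 0-based marker indices
    per_profile: dict  # individual -> sorted consistent indices
    flank_mode: str = "inner"


def consistent_span(profile: RecombinantProfile, model: InheritanceModel) -> set[int]:
    """0-based marker indices where the QTL could reside for this individual.

    A marker is consistent when the model's prediction for its call equals
    the observed phenotype; missing calls are uninformative and counted as
    consistent (logged).
    """
    if not profile.calls:
        raise ValueError(f"profile {profile.individual} has no marker calls")
    out = set()
    for i, call in enumerate(profile.calls):
        predicted = model.predict(call)
        if predicted is None:
            logger.info(
                "missing call at marker %d for %s treated as uninformative",
                i, profile.individual,
            )
            out.add(i)
        elif predicted == profile.phenotype:
            out.add(i)
    return out


def map_interval(
    profiles: Sequence[RecombinantProfile],
    model: InheritanceModel,
    marker_positions: Sequence[int],
    flank_mode: str = "inner",
) -> MappingResult:
    """Intersect consistent spans across recombinants into a bp interval.

    With ``flank_mode="inner"`` the interval runs from the leftmost to the
    rightmost consistent marker position; with ``"flanking"`` it extends to
    the nearest inconsistent marker on each side (or the panel ends).  Zero
    profiles map to the full marker span.  An empty intersection yields a
    structured no-consistent-placement result, never an exception.
    """
    if flank_mode not in ("inner", "flanking"):
        raise ValueError("flank_mode must be 'inner' or 'flanking'")
    positions = [int(p) for p in marker_positions]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("marker positions must be strictly increasing")
    n = len(positions)

    per_profile = {}
    consistent = set(range(n))
    for prof in profiles:
        if len(prof.calls) != n:
            raise ValueError(
                f"profile {prof.individual} has {len(prof.calls)} calls for "
                f"{n} markers"
            )
        span = consistent_span(prof, model)
        per_profile[prof.individual] = sorted(span)
        consistent &= span

    if not consistent:
        return MappingResult(
            status="no_consistent_placement",
            left_bp=None,
            right_bp=None,
            consistent_indices=frozenset(),
            per_profile=per_profile,
            flank_mode=flank_mode,
        )

    lo, hi = min(consistent), max(consistent)
    if flank_mode == "flanking":
        lo = max(lo - 1, 0)
        hi = min(hi + 1, n - 1)
    return MappingResult(
        status="ok",
        left_bp=positions[lo],
        right_bp=positions[hi],
        consistent_indices=frozenset(consistent),
        per_profile=per_profile,
        flank_mode=flank_mode,
    )


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_marker_panel(path) -> list[tuple[str, str, int]]:
    """Marker panel TSV with columns marker, chrom, pos."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    return [(r.marker, r.chrom, int(r.pos)) for r in df.itertuples(index=False)]


def read_profiles(path, markers: Sequence[tuple[str, str, int]]) -> list[RecombinantProfile]:
    """Profile TSV: individual, phenotype, [generation], one column per marker."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    marker_ids = [m[0] for m in markers]
    missing = [m for m in marker_ids if m not in df.columns]
    if missing:
        raise ValueError(f"profile table lacks marker columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RecombinantProfile(
                individual=row.individual,
                phenotype=row.phenotype,
                generation=getattr(row, "generation", "F2"),
                calls=[getattr(row, m) for m in marker_ids],
            )
        )
    return out


def write_report(result: MappingResult, markers, path) -> None:
    import json

    payload = {
        "status": result.status,
        "interval": (
            None
            if result.left_bp is None
            else {"left_bp": result.left_bp, "right_bp": result.right_bp}
        ),
        "flank_mode": result.flank_mode,
        "consistent_markers": [
            markers[i][0] for i in sorted(result.consistent_indices)
        ],
        "per_profile_consistent": {
            k: [markers[i][0] for i in v] for k, v in result.per_profile.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
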