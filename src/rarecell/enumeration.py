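"""Rare-cell enumeration normalized to cells per mL of blood.

A slide carries the nucleated cells of a known-concentration blood aliquot, so
the blood volume it represents is recovered from the total number of detected
nucleated events and the sample's white-blood-cell concentration:
``ml_analyzed = total_events / wbc_per_ml``. Phenotype counts divided by that
volume give (possibly fractional) cells/mL. Counts are never rounded; a
7.5 mL draw plated over ~14 slides corresponds to ~0.5 mL per slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .phenotypes import CELL_TYPES


def volume_per_slide(draw_ml: float, n_slides: int) -> float:
    """Nominal blood volume plated per slide: draw volume / number of slides."""
    if draw_ml <= 0:
        raise ValueError("draw_ml must be positive")
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    return draw_ml / n_slides


def ml_analyzed(total_nucleated_events: float, wbc_per_ml: float) -> float:
    """Blood volume a slide represents, from its event total and WBC concentration."""
    if total_nucleated_events <= 0:
        raise ValueError("total_nucleated_events must be positive")
    if wbc_per_ml <= 0:
        raise ValueError("wbc_per_ml must be positive")
    return total_nucleated_events / wbc_per_ml


@dataclass
class SlideCensus:
    """Raw per-slide counts: total nucleated events and per-phenotype tallies."""

    slide_id: str
    total_nucleated_events: int
    wbc_per_ml: float
    counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.wbc_per_ml <= 0:
            raise ValueError("wbc_per_ml must be positive")
        if self.total_nucleated_events <= 0:
            raise ValueError("total_nucleated_events must be positive")
        unknown = set(self.counts) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown phenotype keys {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative phenotype count")
        if sum(self.counts.values()) > self.total_nucleated_events:
            raise ValueError("phenotype counts exceed total nucleated events")


@dataclass
class NormalizedCounts:
    """Per-phenotype cells/mL (fractional allowed) and the derived volume."""

    slide_id: str
    ml_analyzed: float
    per_ml: dict[str, float]


def normalize_counts(census: SlideCensus) -> NormalizedCounts:
    """Divide every phenotype count by the slide's analyzed blood volume."""
    census.validate()
    ml = ml_analyzed(census.total_nucleated_events, census.wbc_per_ml)
    per_ml = {t: census.counts.get(t, 0) / ml for t in CELL_TYPES}
    return NormalizedCounts(census.slide_id, ml, per_ml)


def merge_censuses(censuses: list[SlideCensus], slide_id: str = "pooled") -> SlideCensus:
    """Pool slides of the same sample (summed events and counts).

    Pooled normalization equals the blood-volume-weighted mean of the per-slide
    cells/mL values. All slides must share the sample's WBC concentration.
    """
    if not censuses:
        raise ValueError("no censuses to merge")
    wbc = censuses[0].wbc_per_ml
    if any(c.wbc_per_ml != wbc for c in censuses):
        raise ValueError("cannot pool slides with differing wbc_per_ml")
    counts: dict[str, int] = {t: 0 for t in CELL_TYPES}
    total = 0
    for c in censuses:
        c.validate()
        total += c.total_nucleated_events
        for t, v in c.counts.items():
            counts[t] += v
    return SlideCensus(slide_id, total, wbc, counts)


def census_from_typed_events(
    typed: pd.DataFrame,
    slide_id: str,
    total_nucleated_events: int,
    wbc_per_ml: float | None = None,
    nominal_volume_ml: float = 0.5,
) -> SlideCensus:
    """Build a census from a typed-event table (``cell_type`` column).

    When the sample's WBC concentration is not supplied, it is estimated as
    total events / nominal plated volume.
    """
    if wbc_per_ml is None:
        wbc_per_ml = total_nucleated_events / nominal_volume_ml
    counts = typed["cell_type"].value_counts().to_dict()
    counts = {t: int(counts.get(t, 0)) for t in CELL_TYPES}
    return SlideCensus(slide_id, int(total_nucleated_events), float(wbc_per_ml), counts)


def cohort_table(rows: list[tuple[str, str, NormalizedCounts]]) -> pd.DataFrame:
    """Assemble (sample_id, cohort, normalized counts) rows into a cohort table.

    Columns: sample_id, cohort, then the 8 phenotype cells/mL columns named
    exactly D, D|CK, D|V, D|CD, D|CK|V, D|CK|CD, D|V|CD, D|CK|V|CD.
    """
    data = []
    for sample_id, cohort, norm in rows:
        data.append({"sample_id": sample_id, "cohort": cohort,
                     **{t: norm.per_ml[t] for t in CELL_TYPES}})
    return pd.DataFrame(data, columns=["sample_id", "cohort", *CELL_TYPES])
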