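"""Titer estimation from decimal dilution-series plate counts.

Viable bacteria (CFU) and infectious phage (PFU) concentrations are
estimated from colony/plaque counts on plates of a 10-fold serial
dilution series.  The estimator is the weighted plate-count formula:
the summed count over the countable plates of (at most) two adjacent
dilution levels is divided by ``n_plates(least dilute level) * 1 +
n_plates(next level) * 0.1``, giving counts per plated aliquot of the
least dilute countable level, then rescaled to per-mL of undiluted
sample by dividing by ``10**exponent * plated_volume``.

When every plate of a series reads zero the result is censored at the
limit of detection rather than reported as zero, so that downstream
log10 transforms remain defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: Approximate cell densities (cells/mL) for McFarland turbidity standards.
DEFAULT_MCFARLAND = {
    0.5: 1.5e8,
    1.0: 3.0e8,
    2.0: 6.0e8,
    3.0: 9.0e8,
    4.0: 1.2e9,
    5.0: 1.5e9,
}

#: Default countable window for plate counts (standard plate-count practice).
DEFAULT_COUNTABLE_RANGE = (10, 300)


@dataclass(frozen=True)
class PlateCount:
    """One plate of a dilution series.

    ``dilution_exponent`` is the decimal exponent applied to the stock
    (e.g. -3 means a 10^-3 dilution was plated); ``plated_volume`` is in
    mL.  ``countable`` is None until :func:`flag_countable` has run.
    """

    sample_id: str
    analyte: str  # "CFU" or "PFU"
    dilution_exponent: int
    plated_volume: float
    count: int
    countable: bool | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ("CFU", "PFU"):
            raise ValueError(f"analyte must be 'CFU' or 'PFU', got {self.analyte!r}")
        if self.dilution_exponent > 0:
            raise ValueError(
                f"dilution exponent must be <= 0, got {self.dilution_exponent}"
            )
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive (mL)")
        if self.count < 0:
            raise ValueError("plate count must be non-negative")


@dataclass(frozen=True)
class DilutionSeries:
    """All plates of one sample's decimal dilution series."""

    sample_id: str
    analyte: str
    plates: tuple[PlateCount, ...]

    def __post_init__(self) -> None:
        if not self.plates:
            raise ValueError("a dilution series needs at least one plate")
        volumes = {p.plated_volume for p in self.plates}
        if len(volumes) > 1:
            raise ValueError(
                f"mixed plated volumes within one series: {sorted(volumes)}"
            )
        for p in self.plates:
            if p.sample_id != self.sample_id or p.analyte != self.analyte:
                raise ValueError("plate metadata disagrees with series metadata")

    @property
    def plated_volume(self) -> float:
        return self.plates[0].plated_volume

    @property
    def exponents(self) -> tuple[int, ...]:
        return tuple(sorted({p.dilution_exponent for p in self.plates}, reverse=True))


@dataclass(frozen=True)
class TiterEstimate:
    """Per-mL concentration estimate for one series.

    ``censored`` means no colony/plaque was observed on any plate; the
    concentration is then to be read as "< limit_of_detection".
    """

    sample_id: str
    analyte: str
    concentration: float
    limit_of_detection: float
    censored: bool
    n_countable_dilutions: int

    @property
    def log10_concentration(self) -> float:
        if self.censored or self.concentration <= 0:
            return math.nan
        return math.log10(self.concentration)


def flag_countable(
    series: DilutionSeries,
    countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
) -> DilutionSeries:
    """Mark each plate countable iff its count lies in ``countable_range``.

    The window is inclusive on both ends; the default 10-300 colonies
    follows standard plate-count practice.
    """
    lo, hi = countable_range
    if not lo < hi:
        raise ValueError(f"countable range must satisfy min < max, got {countable_range}")
    plates = tuple(
        replace(p, countable=bool(lo <= p.count <= hi)) for p in series.plates
    )
    return replace(series, plates=plates)


def weighted_count_estimate(series: DilutionSeries) -> TiterEstimate:
    """Weighted plate-count titer estimate for one flagged series.

    Uses the countable plates of at most two adjacent decimal dilution
    levels.  With plate counts c_ij at the least dilute countable
    exponent e_low (n1 plates) and at e_low - 1 (n2 plates)::

        per_aliquot = sum(c_ij) / (n1 * 1 + n2 * 0.1)
        concentration = per_aliquot / (10**e_low * plated_volume)

    Countability selects the dilution *levels* that enter the formula
    (a level is in if any of its plates is countable); every plate of a
    selected level then contributes to the count total and the plate
    numbers, since at the second level counts naturally fall below the
    countable window.  If more than two consecutive levels qualify, the
    extra levels are dropped from the less-dilute end (and logged).
    Countable plates at non-adjacent decimal levels indicate a
    dilution-series anomaly and raise.  A series with no countable
    plate and all-zero counts is censored at the limit of detection of
    its least dilute level.
    """
    if any(p.countable is None for p in series.plates):
        raise ValueError("series not flagged; run flag_countable first")

    vol = series.plated_volume
    countable = [p for p in series.plates if p.countable]

    if not countable:
        if all(p.count == 0 for p in series.plates):
            e_min = max(p.dilution_exponent for p in series.plates)  # least dilute
            lod = 1.0 / (10.0**e_min * vol)
            return TiterEstimate(
                sample_id=series.sample_id,
                analyte=series.analyte,
                concentration=0.0,
                limit_of_detection=lod,
                censored=True,
                n_countable_dilutions=0,
            )
        raise ValueError(
            f"series {series.sample_id!r}: no countable plate but nonzero counts "
            "(dilution-series anomaly)"
        )

    # Dilution levels with countable plates, least dilute (largest 10**e) first.
    levels = sorted({p.dilution_exponent for p in countable}, reverse=True)
    if len(levels) > 2:
        dropped = levels[:-2]
        log.warning(
            "series %s: %d countable dilution levels; dropping less-dilute "
            "levels %s from the estimate",
            series.sample_id,
            len(levels),
            dropped,
        )
        levels = levels[-2:]
    if len(levels) == 2 and levels[0] - levels[1] != 1:
        raise ValueError(
            f"series {series.sample_id!r}: countable plates at non-adjacent "
            f"decimal levels {levels} (dilution-series anomaly)"
        )

    e_low = levels[0]
    kept = [p for p in series.plates if p.dilution_exponent in levels]
    n1 = sum(1 for p in kept if p.dilution_exponent == e_low)
    n2 = len(kept) - n1
    total = sum(p.count for p in kept)
    per_aliquot = total / (n1 * 1.0 + n2 * 0.1)
    concentration = per_aliquot / (10.0**e_low * vol)

    e_min = max(p.dilution_exponent for p in series.plates)
    return TiterEstimate(
        sample_id=series.sample_id,
        analyte=series.analyte,
        concentration=concentration,
        limit_of_detection=1.0 / (10.0**e_min * vol),
        censored=False,
        n_countable_dilutions=len(levels),
    )


def estimate_titer(
    series: DilutionSeries,
    countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
) -> TiterEstimate:
    """Convenience wrapper: flag countability, then estimate."""
    return weighted_count_estimate(flag_countable(series, countable_range))


def compute_moi(pfu_added: float, cfu_present: float) -> float:
    """Input multiplicity of infection: phage added per bacterium present."""
    if cfu_present <= 0:
        raise ValueError("cfu_present must be positive to define an MOI")
    if pfu_added < 0:
        raise ValueError("pfu_added must be non-negative")
    return pfu_added / cfu_present


def mcfarland_to_density(
    standard: float, table: dict[float, float] | None = None
) -> float:
    """Approximate cells/mL for a McFarland turbidity standard."""
    table = DEFAULT_MCFARLAND if table is None else table
    key = float(standard)
    if key not in table:
        raise ValueError(
            f"McFarland standard {standard} not in table {sorted(table)}"
        )
    return table[key]


def make_series(
    sample_id: str,
    analyte: str,
    counts_by_exponent: dict[int, Sequence[int]],
    plated_volume: float,
) -> DilutionSeries:
    """Build a :class:`DilutionSeries` from a {exponent: [counts]} mapping."""
    plates = tuple(
        PlateCount(sample_id, analyte, e, plated_volume, int(c))
        for e in sorted(counts_by_exponent, reverse=True)
        for c in counts_by_exponent[e]
    )
    return DilutionSeries(sample_id, analyte, plates)
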