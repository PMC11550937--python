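"""Efficiency of plating (EOP) and host-range grading.

EOP is the ratio of a phage's titer on a test bacterial isolate to its
titer on the original host.  Each phage x isolate pair is graded on a
six-level sensitivity scale:

=================  =============================================
no_sensitivity     no plaque formation
moderately_low     opaque (turbid) plaque only, no countable lysis
low                EOP < 0.1
moderate           0.1 <= EOP <= 1
high               1 < EOP <= 10
ultimate           EOP > 10
=================  =============================================

The grades over all pairs form the host-range matrix, summarized per
phage as the fraction of isolates showing any sensitivity and rendered
as a categorical heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Grade(str, Enum):
    NO_SENSITIVITY = "no_sensitivity"
    MODERATELY_LOW = "moderately_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    ULTIMATE = "ultimate"


#: Heatmap palette, one colour per grade in scale order.
GRADE_COLORS = {
    Grade.NO_SENSITIVITY: "#08306b",  # dark blue
    Grade.MODERATELY_LOW: "#9ecae1",  # light blue
    Grade.LOW: "#969696",  # grey
    Grade.MODERATE: "#fdd0a2",  # light orange
    Grade.HIGH: "#e6550d",  # dark orange
    Grade.ULTIMATE: "#a50f15",  # red
}

GRADE_ORDER = list(GRADE_COLORS)


@dataclass(frozen=True)
class SpotResult:
    """One replicate spot/plaque observation for a phage on an isolate.

    ``outcome`` is "count" (plaques counted), "opaque" (turbid plaque
    only) or "none" (no plaque).  ``plaque_count`` is present iff
    outcome is "count".
    """

    phage_id: str
    isolate_id: str
    replicate: int
    outcome: str
    plaque_count: int | None = None
    dilution_exponent: int = 0
    plated_volume: float = 0.1

    def __post_init__(self) -> None:
        if self.outcome not in ("count", "opaque", "none"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "count") != (self.plaque_count is not None):
            raise ValueError("plaque_count must be present iff outcome == 'count'")
        if self.plaque_count is not None and self.plaque_count < 0:
            raise ValueError("plaque_count must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive (mL)")


@dataclass(frozen=True)
class EOPRecord:
    """Aggregated EOP and grade for one phage x isolate cell."""

    phage_id: str
    isolate_id: str
    eop: float | None
    grade: Grade
    n_replicates: int


@dataclass(frozen=True)
class HostRangeMatrix:
    """Complete grade matrix: exactly one record per phage x isolate pair."""

    phages: tuple[str, ...]
    isolates: tuple[str, ...]
    records: tuple[EOPRecord, ...]

    def __post_init__(self) -> None:
        pairs = {(r.phage_id, r.isolate_id) for r in self.records}
        expected = {(p, i) for p in self.phages for i in self.isolates}
        if pairs != expected:
            missing = expected - pairs
            extra = pairs - expected
            raise ValueError(
                f"incomplete host-range matrix (missing {len(missing)}, "
                f"unexpected {len(extra)} cells)"
            )
        if len(self.records) != len(expected):
            raise ValueError("duplicate cells in host-range matrix")

    def record(self, phage_id: str, isolate_id: str) -> EOPRecord:
        for r in self.records:
            if r.phage_id == phage_id and r.isolate_id == isolate_id:
                return r
        raise KeyError((phage_id, isolate_id))

    def to_eop_frame(self) -> pd.DataFrame:
        """Numeric EOP matrix (NaN where no numeric EOP), phages as rows."""
        df = pd.DataFrame(np.nan, index=list(self.phages), columns=list(self.isolates))
        for r in self.records:
            if r.eop is not None:
                df.loc[r.phage_id, r.isolate_id] = r.eop
        return df

    def to_grade_frame(self) -> pd.DataFrame:
        """Categorical grade matrix, phages as rows."""
        df = pd.DataFrame("", index=list(self.phages), columns=list(self.isolates))
        for r in self.records:
            df.loc[r.phage_id, r.isolate_id] = r.grade.value
        return df


def compute_eop(test_titer: float, reference_titer: float) -> float:
    """EOP = titer on the test isolate / titer on the original host."""
    if reference_titer <= 0:
        raise ValueError("reference titer must be positive")
    if test_titer < 0:
        raise ValueError("test titer must be non-negative")
    return test_titer / reference_titer


def grade_eop(eop: float | None = None, outcome: str | None = None) -> Grade:
    """Map an EOP value or a categorical outcome to a sensitivity grade.

    Boundary policy follows the printed thresholds: EOP of exactly 0.1
    and 1 are moderate, exactly 10 is high.  EOP of exactly 0 means no
    plaque formed and is graded no_sensitivity.
    """
    if outcome is not None:
        if outcome == "none":
            return Grade.NO_SENSITIVITY
        if outcome == "opaque":
            return Grade.MODERATELY_LOW
        raise ValueError(f"outcome must be 'none' or 'opaque', got {outcome!r}")
    if eop is None:
        raise ValueError("provide either an EOP value or an outcome")
    if eop < 0:
        raise ValueError("EOP must be non-negative")
    if eop == 0:
        return Grade.NO_SENSITIVITY
    if eop < 0.1:
        return Grade.LOW
    if eop <= 1:
        return Grade.MODERATE
    if eop <= 10:
        return Grade.HIGH
    return Grade.ULTIMATE


def aggregate_replicates(
    spots: Sequence[SpotResult], reference_titer: float
) -> EOPRecord:
    """Collapse one cell's replicate spots into a single EOP record.

    Replicate plaque counts are converted to per-replicate titers,
    averaged at the titer level, and one EOP is computed from the mean
    (reducing ratio-of-means bias).  "none" replicates mixed with counts
    contribute zero counts; all-"none" cells grade no_sensitivity and
    all-"opaque" cells moderately_low.  Opaque replicates alongside
    numeric counts are excluded from the titer mean (numeric evidence
    dominates).
    """
    if not spots:
        raise ValueError("no replicates supplied")
    phage = {s.phage_id for s in spots}
    isolate = {s.isolate_id for s in spots}
    if len(phage) != 1 or len(isolate) != 1:
        raise ValueError("replicates must come from a single phage x isolate pair")
    if reference_titer <= 0:
        raise ValueError("reference titer must be positive")

    outcomes = [s.outcome for s in spots]
    n = len(spots)
    if all(o == "none" for o in outcomes):
        return EOPRecord(spots[0].phage_id, spots[0].isolate_id, None,
                         Grade.NO_SENSITIVITY, n)
    if all(o == "opaque" for o in outcomes):
        return EOPRecord(spots[0].phage_id, spots[0].isolate_id, None,
                         Grade.MODERATELY_LOW, n)

    if any(o == "count" for o in outcomes):
        titers = [
            (s.plaque_count if s.outcome == "count" else 0)
            / (10.0**s.dilution_exponent * s.plated_volume)
            for s in spots
            if s.outcome != "opaque"
        ]
    else:  # mixture of opaque and none only: opaque evidence wins
        return EOPRecord(spots[0].phage_id, spots[0].isolate_id, None,
                         Grade.MODERATELY_LOW, n)

    mean_titer = float(np.mean(titers))
    eop = compute_eop(mean_titer, reference_titer)
    return EOPRecord(spots[0].phage_id, spots[0].isolate_id, eop, grade_eop(eop), n)


def build_matrix(
    spots: Iterable[SpotResult], reference_titers: Mapping[str, float]
) -> HostRangeMatrix:
    """Aggregate a flat collection of spot replicates into a grade matrix.

    Phage and isolate ordering follows first appearance in the input.
    Every phage must have a reference titer (on its original host).
    """
    cells: dict[tuple[str, str], list[SpotResult]] = {}
    phages: list[str] = []
    isolates: list[str] = []
    for s in spots:
        if s.phage_id not in phages:
            phages.append(s.phage_id)
        if s.isolate_id not in isolates:
            isolates.append(s.isolate_id)
        cells.setdefault((s.phage_id, s.isolate_id), []).append(s)

    records = []
    for (p, i), cell in cells.items():
        if p not in reference_titers:
            raise ValueError(f"no reference titer for phage {p!r}")
        records.append(aggregate_replicates(cell, reference_titers[p]))
    return HostRangeMatrix(tuple(phages), tuple(isolates), tuple(records))


def summarize_host_range(matrix: HostRangeMatrix) -> pd.DataFrame:
    """Per-phage susceptibility summary.

    An isolate counts as susceptible for every grade except
    no_sensitivity (opaque-only cells count as positive lytic activity).
    Percentages are rounded to one decimal.
    """
    rows = []
    for p in matrix.phages:
        recs = [r for r in matrix.records if r.phage_id == p]
        n_total = len(recs)
        n_susc = sum(1 for r in recs if r.grade is not Grade.NO_SENSITIVITY)
        rows.append(
            {
                "phage_id": p,
                "n_susceptible": n_susc,
                "n_total": n_total,
                "pct_susceptible": round(100.0 * n_susc / n_total, 1),
            }
        )
    return pd.DataFrame(rows)


def render_heatmap(matrix: HostRangeMatrix, path: str) -> None:
    """Write the grade matrix as a categorical heatmap (PNG or SVG).

    Phages on the x-axis, isolates on the y-axis, input order preserved;
    the legend lists all six grades.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    if not matrix.phages or not matrix.isolates:
        raise ValueError("cannot render an empty host-range matrix")

    grade_index = {g: k for k, g in enumerate(GRADE_ORDER)}
    data = np.zeros((len(matrix.isolates), len(matrix.phages)), dtype=int)
    iso_pos = {i: k for k, i in enumerate(matrix.isolates)}
    ph_pos = {p: k for k, p in enumerate(matrix.phages)}
    for r in matrix.records:
        data[iso_pos[r.isolate_id], ph_pos[r.phage_id]] = grade_index[r.grade]

    cmap = ListedColormap([GRADE_COLORS[g] for g in GRADE_ORDER])
    plt.rcParams["svg.fonttype"] = "none"  # keep legend text searchable in SVG
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * len(matrix.phages) + 2),
                 max(3, 0.22 * len(matrix.isolates) + 1))
    )
    ax.imshow(data, cmap=cmap, vmin=0, vmax=len(GRADE_ORDER) - 1, aspect="auto")
    ax.set_xticks(range(len(matrix.phages)), matrix.phages, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.isolates)), matrix.isolates, fontsize=6)
    ax.set_xlabel("phage")
    ax.set_ylabel("bacterial isolate")
    handles = [
        Patch(facecolor=GRADE_COLORS[g], label=g.value.replace("_", " "))
        for g in GRADE_ORDER
    ]
    ax.legend(handles=handles, bbox_to_anchor=(1.02, 1), loc="upper left",
              fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
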