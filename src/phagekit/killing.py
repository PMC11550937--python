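"""Planktonic killing-assay analytics: AUC and virulence index.

A killing assay co-incubates a bacterial isolate with a phage at a
given input MOI and records OD600 hourly, alongside a phage-free
growth control.  Growth suppression is summarized by the area under
the OD600-time curve (trapezoidal rule) and by the virulence index

    V = 100 * (1 - AUC_treatment / AUC_control)

so that V = 0 means no effect and V = 100 complete suppression; V is
not clamped (negative values mean the treated culture grew more) but
out-of-range values are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stats import TestResult, two_sample_test


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series.

    Controls (no phage) have ``phage_id`` and ``moi`` set to None.
    Times are in hours and strictly increasing.
    """

    well_id: str
    isolate_id: str
    phage_id: str | None
    moi: float | None
    replicate: int
    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od600", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValueError("times and od600 must be 1-D and equally long")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(od[~np.isnan(od)] < 0):
            raise ValueError("OD600 values must be non-negative")

    @property
    def is_control(self) -> bool:
        return self.phage_id is None


@dataclass(frozen=True)
class KillingAssayResult:
    """Per (phage, MOI) condition summary against its growth control."""

    phage_id: str
    isolate_id: str
    moi: float
    auc_treatment: float
    auc_control: float
    virulence_index: float
    replicate_aucs_treatment: tuple[float, ...]
    replicate_aucs_control: tuple[float, ...]
    per_replicate_virulence: tuple[float, ...]
    comparison: TestResult | None
    flag: str | None = None  # set when V falls outside [0, 100]


def compute_auc(
    curve: GrowthCurve,
    baseline: str = "raw",
    blank: float = 0.0,
    window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal area under the OD600 curve, in OD*h.

    ``baseline``: "raw" integrates the reported OD; "subtract_t0"
    subtracts the first reading; "subtract_blank" subtracts ``blank``.
    Negative post-baseline values are clipped at zero.  ``window``
    restricts integration to times within [start, stop].
    """
    t = curve.times
    y = curve.od600
    if np.any(np.isnan(y)):
        raise ValueError(f"well {curve.well_id}: NaN OD values (read failure?)")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if len(t) < 2:
        raise ValueError("AUC needs at least two time points")
    if baseline == "raw":
        pass
    elif baseline == "subtract_t0":
        y = y - y[0]
    elif baseline == "subtract_blank":
        y = y - blank
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    y = np.clip(y, 0.0, None)
    return float(np.trapezoid(y, t))


def virulence_index(auc_treatment: float, auc_control: float) -> float:
    """V = 100 * (1 - AUC_treatment / AUC_control), on a 0-100 scale."""
    if auc_control <= 0:
        raise ValueError("control AUC must be positive")
    if auc_treatment < 0:
        raise ValueError("treatment AUC must be non-negative")
    return 100.0 * (1.0 - auc_treatment / auc_control)


def analyze_assay(
    curves: Iterable[GrowthCurve],
    alpha: float = 0.05,
    baseline: str = "raw",
    blank: float = 0.0,
    window: tuple[float, float] | None = None,
) -> list[KillingAssayResult]:
    """Full killing-assay analysis for a plate of growth curves.

    Curves are grouped by (isolate, phage, MOI); each treatment
    condition is matched to the phage-free control curves of the same
    isolate.  Per condition this computes replicate AUCs, the mean-AUC
    virulence index (with per-replicate indices reported alongside) and
    a treatment-vs-control location test: Shapiro-Wilk normality gate at
    ``alpha``, then Welch's t-test or the rank-sum fallback.  The
    comparison is skipped (None) when either side has fewer than two
    replicates.

    Raises if a treatment has no matched control or if time grids
    disagree within a comparison (plate misalignment).
    """
    curves = list(curves)
    controls: dict[str, list[GrowthCurve]] = {}
    treatments: dict[tuple[str, str, float], list[GrowthCurve]] = {}
    for c in curves:
        if c.is_control:
            controls.setdefault(c.isolate_id, []).append(c)
        else:
            treatments.setdefault((c.isolate_id, c.phage_id, c.moi), []).append(c)

    results = []
    for (isolate, phage, moi), group in treatments.items():
        ctrl = controls.get(isolate)
        if not ctrl:
            raise ValueError(
                f"no phage-free control for isolate {isolate!r} "
                f"(needed by {phage!r} at MOI {moi})"
            )
        grid = group[0].times
        for c in group + ctrl:
            if len(c.times) != len(grid) or not np.allclose(c.times, grid):
                raise ValueError(
                    f"unequal time grids within comparison for isolate "
                    f"{isolate!r} (plate misalignment)"
                )
        auc_t = [compute_auc(c, baseline, blank, window) for c in group]
        auc_c = [compute_auc(c, baseline, blank, window) for c in ctrl]
        mean_t, mean_c = float(np.mean(auc_t)), float(np.mean(auc_c))
        v = virulence_index(mean_t, mean_c)
        per_rep_v = tuple(virulence_index(a, mean_c) for a in auc_t)
        comparison = (
            two_sample_test(np.array(auc_t), np.array(auc_c), alpha=alpha)
            if len(auc_t) >= 2 and len(auc_c) >= 2
            else None
        )
        results.append(
            KillingAssayResult(
                phage_id=phage,
                isolate_id=isolate,
                moi=moi,
                auc_treatment=mean_t,
                auc_control=mean_c,
                virulence_index=v,
                replicate_aucs_treatment=tuple(auc_t),
                replicate_aucs_control=tuple(auc_c),
                per_replicate_virulence=per_rep_v,
                comparison=comparison,
                flag="virulence index outside [0, 100]"
                if not 0.0 <= v <= 100.0
                else None,
            )
        )
    return results
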