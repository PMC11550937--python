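"""Phage-bacteria co-culture simulator and synthetic assay inputs.

Every input the analysis pipeline consumes can be generated here with
known truth: OD600 co-culture curves, decimal dilution-series plate
counts, host-range spot records, and explant endpoint concentrations.

The co-culture model is standard mass-action phage ecology with an
exponentially distributed latent stage.  Susceptible (S), infected (I)
and phage-resistant (R) cells share logistic growth toward carrying
capacity K; free phage (P) adsorb to susceptible cells at rate delta,
lysed cells release beta progeny after a mean latent period tau, and
free phage decay at rate lam.  A first-order leak mu_res moves
susceptible cells into the resistant class, the simplest mechanism
able to produce weaker net killing at higher phage dose:

    dS/dt = r S (1 - N/K) - delta S P - mu_res S
    dR/dt = r R (1 - N/K) + mu_res S
    dI/dt = delta S P - I/tau
    dP/dt = (beta/tau) I - delta N P - lam P,     N = S + I + R

Optical density reports total intact cells (lysed cells contribute
nothing): OD(t) = od_per_cell * N(t) + Gaussian noise truncated at 0.

Randomness is governed by one global seed; each well/stream draws from
an independent counter-indexed substream so individual wells are
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .host_range import SpotResult
from .killing import GrowthCurve
from .quantify import DilutionSeries, PlateCount


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for stream (seed; keys...), bit-reproducible."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=tuple(keys)))


@dataclass(frozen=True)
class CocultureParams:
    """Parameters of the co-culture model (units in field comments).

    Defaults describe a fast-growing streptococcal culture with a
    moderately lytic phage: doubling time just under an hour, carrying
    capacity 1e9 cells/mL, a 30-minute latent period and burst size 50.
    """

    r: float = 0.8  # intrinsic growth rate, 1/h
    K: float = 1e9  # carrying capacity, cells/mL
    delta: float = 1e-9  # adsorption rate constant, mL/(PFU*h)
    tau: float = 0.5  # mean latent period, h
    beta: float = 50.0  # burst size, PFU per lysed cell
    lam: float = 0.01  # free-phage decay rate, 1/h
    mu_res: float = 0.0  # resistant-mutant emergence rate, 1/h
    od_per_cell: float = 1e-9  # OD600 units per (cell/mL)
    noise_sd: float = 0.0  # additive OD noise sd
    S0: float = 1e6  # initial susceptible cells/mL
    P0: float = 1e6  # initial free phage PFU/mL

    def __post_init__(self) -> None:
        nonneg = ("r", "delta", "beta", "lam", "mu_res", "noise_sd", "S0", "P0")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("K", "tau", "od_per_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimulatedAssay:
    """A simulated killing assay plus the truth that generated it."""

    curves: tuple[GrowthCurve, ...]
    truth: dict

    def __post_init__(self) -> None:
        grid = self.curves[0].times
        for c in self.curves:
            if len(c.times) != len(grid) or not np.allclose(c.times, grid):
                raise ValueError("all simulated curves must share one time grid")


def _rhs(t: float, y: np.ndarray, p: CocultureParams) -> list[float]:
    S, I, R, P = np.maximum(y, 0.0)
    N = S + I + R
    growth = p.r * (1.0 - N / p.K)
    dS = growth * S - p.delta * S * P - p.mu_res * S
    dI = p.delta * S * P - I / p.tau
    dR = growth * R + p.mu_res * S
    dP = (p.beta / p.tau) * I - p.delta * N * P - p.lam * P
    return [dS, dI, dR, dP]


def integrate_coculture(
    params: CocultureParams, t_grid: np.ndarray
) -> np.ndarray:
    """Integrate the compartment model on ``t_grid``; rows are S, I, R, P.

    Stiff-safe adaptive integration (LSODA) with state non-negativity
    enforced by evaluating rates on clamped states and clamping the
    reported trajectory at zero; burst terms make the system stiff at
    large beta/tau ratios.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be 1-D, strictly increasing, length >= 2")
    if t_grid[0] != 0:
        raise ValueError("time grid must start at 0")
    y0 = [params.S0, 0.0, 0.0, params.P0]
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_grid[-1])),
        y0,
        t_eval=t_grid,
        args=(params,),
        method="LSODA",
        rtol=1e-8,
        atol=1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return np.maximum(sol.y, 0.0)


def simulate_growth_curve(
    params: CocultureParams,
    t_grid: Sequence[float],
    seed: int,
    *,
    well_id: str = "sim",
    isolate_id: str = "isolate",
    phage_id: str | None = "phage",
    moi: float | None = None,
    replicate: int = 1,
) -> GrowthCurve:
    """One simulated OD600 well.

    With ``noise_sd == 0`` the output is deterministic given the
    parameters (the seed is unused).  A phage-free well should be
    requested with ``P0 = 0`` and ``phage_id = None``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    states = integrate_coculture(params, t_grid)
    n_cells = states[0] + states[1] + states[2]
    od = params.od_per_cell * n_cells
    if params.noise_sd > 0:
        rng = substream(seed)
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    return GrowthCurve(
        well_id=well_id,
        isolate_id=isolate_id,
        phage_id=phage_id,
        moi=moi,
        replicate=replicate,
        times=t_grid,
        od600=od,
    )


def simulate_assay(
    params: CocultureParams,
    mois: Sequence[float] = (1.0, 10.0),
    n_replicates: int = 3,
    t_grid: Sequence[float] | None = None,
    seed: int = 0,
    isolate_id: str = "isolate-10",
    phage_id: str = "phage-1",
) -> SimulatedAssay:
    """A full killing assay: phage-free controls plus one treatment per MOI.

    Treatments start from ``P0 = moi * S0``; each well draws noise from
    its own substream of ``seed``.  Defaults (MOI 1 and 10, triplicate,
    hourly 0-24 h readings) match a standard 24 h plate-reader run.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 25.0)
    t_grid = np.asarray(t_grid, dtype=float)

    # One deterministic trajectory per distinct initial phage load; noise is
    # redrawn per well from its own substream.
    od_cache: dict[float, np.ndarray] = {}

    def _noiseless_od(p0: float) -> np.ndarray:
        if p0 not in od_cache:
            states = integrate_coculture(_with(params, P0=p0, noise_sd=0.0), t_grid)
            od_cache[p0] = params.od_per_cell * (states[0] + states[1] + states[2])
        return od_cache[p0]

    def _well(p0: float, stream: int, **meta) -> GrowthCurve:
        od = _noiseless_od(p0)
        if params.noise_sd > 0:
            od = od + substream(seed, stream).normal(0.0, params.noise_sd, len(od))
        return GrowthCurve(times=t_grid, od600=np.maximum(od, 0.0), **meta)

    curves: list[GrowthCurve] = []
    stream = 0
    for rep in range(1, n_replicates + 1):
        curves.append(
            _well(0.0, stream, well_id=f"C{rep}", isolate_id=isolate_id,
                  phage_id=None, moi=None, replicate=rep)
        )
        stream += 1
    for moi in mois:
        for rep in range(1, n_replicates + 1):
            curves.append(
                _well(moi * params.S0, stream, well_id=f"M{moi:g}R{rep}",
                      isolate_id=isolate_id, phage_id=phage_id, moi=moi,
                      replicate=rep)
            )
            stream += 1
    truth = {
        "params": asdict(params),
        "mois": list(mois),
        "n_replicates": n_replicates,
        "seed": seed,
        "treatment_P0": {f"{m:g}": m * params.S0 for m in mois},
    }
    return SimulatedAssay(tuple(curves), truth)


def _with(params: CocultureParams, **updates) -> CocultureParams:
    from dataclasses import replace

    return replace(params, **updates)


def simulate_dilution_series(
    true_conc: float,
    dilution_exponents: Sequence[int],
    plated_volume: float,
    n_plates_per_dilution: int,
    seed: int,
    *,
    sample_id: str = "sim",
    analyte: str = "CFU",
) -> DilutionSeries:
    """Poisson plate counts from a known true concentration.

    Each plate at exponent e draws Poisson with mean
    ``true_conc * 10**e * plated_volume``.
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    if plated_volume <= 0:
        raise ValueError("plated volume must be positive")
    if n_plates_per_dilution < 1:
        raise ValueError("need at least one plate per dilution")
    if any(e > 0 for e in dilution_exponents):
        raise ValueError("dilution exponents must be <= 0")
    rng = substream(seed)
    plates = []
    for e in sorted(dilution_exponents, reverse=True):
        mean = true_conc * 10.0**e * plated_volume
        for _ in range(n_plates_per_dilution):
            plates.append(
                PlateCount(sample_id, analyte, int(e), plated_volume,
                           int(rng.poisson(mean)))
            )
    return DilutionSeries(sample_id, analyte, tuple(plates))


def simulate_host_range(
    true_eop,
    ref_titer,
    plated_volume: float = 0.1,
    seed: int = 0,
    dilution_exponent: int = -6,
    n_replicates: int = 3,
) -> list[SpotResult]:
    """Triplicate spot records for a known phage x isolate EOP matrix.

    ``true_eop`` is a DataFrame (rows = phages, columns = isolates):
    NaN marks a non-infective pair (outcome "none"), the sentinel -1 an
    opaque-only pair, any other non-negative value the true EOP.
    ``ref_titer`` maps each phage to its titer on the original host
    (PFU/mL); plaque counts are Poisson with mean
    ``ref_titer * eop * 10**exponent * plated_volume``.
    """
    import pandas as pd

    true_eop = pd.DataFrame(true_eop)
    for phage in true_eop.index:
        if phage not in ref_titer or ref_titer[phage] <= 0:
            raise ValueError(f"positive reference titer required for phage {phage!r}")
    vals = true_eop.to_numpy(dtype=float)
    bad = vals[(~np.isnan(vals)) & (vals < 0) & (vals != -1)]
    if bad.size:
        raise ValueError("negative EOP values other than the -1 opaque sentinel")

    rng = substream(seed)
    spots: list[SpotResult] = []
    for phage in true_eop.index:
        for isolate in true_eop.columns:
            eop = true_eop.loc[phage, isolate]
            for rep in range(1, n_replicates + 1):
                if np.isnan(eop):
                    spots.append(SpotResult(phage, isolate, rep, "none",
                                            None, dilution_exponent, plated_volume))
                elif eop == -1:
                    spots.append(SpotResult(phage, isolate, rep, "opaque",
                                            None, dilution_exponent, plated_volume))
                else:
                    mean = (ref_titer[phage] * eop * plated_volume
                            * 10.0**dilution_exponent)
                    spots.append(
                        SpotResult(phage, isolate, rep, "count",
                                   int(rng.poisson(mean)),
                                   dilution_exponent, plated_volume)
                    )
    return spots


def simulate_explant_endpoint(
    mean_log10: float, sd_log10: float, n: int, seed: int
) -> np.ndarray:
    """Log-normal per-mL endpoint concentrations: 10**Normal(mean, sd)."""
    if sd_log10 < 0:
        raise ValueError("sd_log10 must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = substream(seed)
    return 10.0 ** rng.normal(mean_log10, sd_log10, size=n)
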