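"""Stochastic population viability analysis under drought scenarios.

Annual projection matrices are partitioned into a drought pool (years
with negative 14-month mean SPEI) and a non-drought pool (positive or
zero).  Each replicate starts 50 ramets at the stable stage
distribution of the study-period mean matrix and is projected 50 years
by i.i.d. annual matrix draws: 90% drought under "increased", uniform
over all annual matrices under "no_change", 10% drought under
"decreased".  A population whose size after 50 years falls below the
starting 50 ramets marks a potentially nonviable trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rametdemog.mpm import ProjectionMatrix, mean_matrix, stable_stage_distribution
from rametdemog.weather import is_drought_year


class PVAError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    """One drought-frequency scenario.

    ``p_drought`` is the probability of drawing from the drought pool
    each year; ``None`` means uniform draws over all annual matrices
    (pool-proportional, the "no change" scenario).
    """

    name: str
    p_drought: float | None
    horizon: int = 50
    replicates: int = 1000
    n0: float = 50.0

    def __post_init__(self):
        if self.p_drought is not None and not 0.0 <= self.p_drought <= 1.0:
            raise PVAError("p_drought must lie in [0, 1]")
        if min(self.horizon, self.replicates) <= 0 or self.n0 <= 0:
            raise PVAError("horizon, replicates and N0 must be positive")


DEFAULT_SCENARIOS = (
    ScenarioSpec("increased", 0.9),
    ScenarioSpec("no_change", None),
    ScenarioSpec("decreased", 0.1),
)


@dataclass
class PVAResult:
    scenario: ScenarioSpec
    final_sizes: np.ndarray
    log_final_sizes: np.ndarray
    drought_draw_fraction: float
    median_final: float = field(init=False)
    frac_below_start: float = field(init=False)

    def __post_init__(self):
        self.median_final = float(np.exp(np.median(self.log_final_sizes)))
        self.frac_below_start = float(
            np.mean(self.log_final_sizes < np.log(self.scenario.n0)))


def partition_matrices(matrices: dict[int, ProjectionMatrix],
                       annual_spei: dict[int, float]
                       ) -> tuple[list, list]:
    """Split annual matrices into (drought, non-drought) pools by the
    sign of each year's mean SPEI (zero counts as non-drought)."""
    missing = sorted(set(matrices) - set(annual_spei))
    if missing:
        raise PVAError(f"no annual SPEI for matrix years {missing}")
    drought, wet = [], []
    for year in sorted(matrices):
        (drought if is_drought_year(annual_spei[year]) else wet).append(
            matrices[year])
    return drought, wet


def project_stochastic(drought_pool, nondrought_pool, spec: ScenarioSpec,
                       rng, start: np.ndarray | None = None) -> PVAResult:
    """Project replicate populations under one scenario.

    Stage vectors are continuous-valued (no demographic stochasticity);
    accumulation is rescaled on the fly so fast-growing replicates
    cannot overflow, and results are reported on both the natural and
    log scales.
    """
    rng = np.random.default_rng(rng)
    drought = [m.A if isinstance(m, ProjectionMatrix) else np.asarray(m, float)
               for m in drought_pool]
    wet = [m.A if isinstance(m, ProjectionMatrix) else np.asarray(m, float)
           for m in nondrought_pool]
    if spec.p_drought is None:
        pools = drought + wet
        n_drought = len(drought)
        if not pools:
            raise PVAError("no matrices to draw from")
    else:
        if spec.p_drought > 0 and not drought:
            raise PVAError(f"scenario {spec.name!r} needs a nonempty drought pool")
        if spec.p_drought < 1 and not wet:
            raise PVAError(f"scenario {spec.name!r} needs a nonempty "
                           "non-drought pool")
    if start is None:
        all_mats = drought_pool if not nondrought_pool else (
            list(drought_pool) + list(nondrought_pool))
        mm = mean_matrix(all_mats) if isinstance(all_mats[0], ProjectionMatrix) \
            else None
        ssd = stable_stage_distribution(mm if mm is not None else all_mats[0])
        start = spec.n0 * ssd
    start = np.asarray(start, dtype=float)
    dim = start.size

    R = spec.replicates
    pop = np.tile(start, (R, 1))
    log_scale = np.zeros(R)
    drought_draws = 0
    total_draws = spec.horizon * R
    for _ in range(spec.horizon):
        if spec.p_drought is None:
            idx = rng.integers(0, len(pools), size=R)
            drought_draws += int(np.sum(idx < n_drought))
            mats, index = pools, idx
        else:
            from_drought = rng.random(R) < spec.p_drought
            drought_draws += int(from_drought.sum())
            idx = np.empty(R, dtype=int)
            nd = int(from_drought.sum())
            if nd:
                idx[from_drought] = rng.integers(0, len(drought), size=nd)
            if R - nd:
                idx[~from_drought] = (rng.integers(0, len(wet), size=R - nd)
                                      + len(drought))
            mats, index = drought + wet, idx
        for j in np.unique(index):
            sel = index == j
            pop[sel] = pop[sel] @ mats[j].T
        totals = pop.sum(axis=1)
        big = totals > 1e200
        if big.any():
            log_scale[big] += np.log(totals[big])
            pop[big] /= totals[big, None]
        dead = totals <= 0
        if dead.any():
            pop[dead] = 0.0
    totals = pop.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_final = np.where(totals > 0, np.log(np.clip(totals, 1e-300, None))
                             + log_scale, -np.inf)
    final = np.exp(np.clip(log_final, None, 700.0))
    return PVAResult(scenario=spec, final_sizes=final,
                     log_final_sizes=log_final,
                     drought_draw_fraction=drought_draws / total_draws)


def run_all_scenarios(drought_pool, nondrought_pool, seed,
                      scenarios=DEFAULT_SCENARIOS,
                      start: np.ndarray | None = None
                      ) -> tuple[dict[str, PVAResult], pd.DataFrame]:
    """Run the three drought-frequency scenarios with per-scenario
    child seeds split from one root seed."""
    root = np.random.default_rng(seed)
    children = root.spawn(len(scenarios))
    results = {}
    rows = []
    for spec, child in zip(scenarios, children):
        res = project_stochastic(drought_pool, nondrought_pool, spec, child,
                                 start=start)
        results[spec.name] = res
        rows.append((spec.name, spec.p_drought, res.median_final,
                     res.frac_below_start, res.drought_draw_fraction))
    table = pd.DataFrame(rows, columns=["scenario", "p_drought",
                                        "median_final", "frac_below_start",
                                        "drought_draw_fraction"])
    return results, table
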