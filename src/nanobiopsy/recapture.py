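"""Lineage Monte-Carlo: can a longitudinal biopsy re-sample the same cell?

A founder cell placed at the centre of the microscope field of view
migrates as a 2-D random walk (half-normal step lengths, uniform
directions), divides and dies with exponential waiting times over a
72-hour course.  The day-4 biopsy picks uniformly among the surviving
in-field lineage cells, because the platform cannot distinguish the
founder from its progeny by eye.  The simulation yields the probability
that the founder itself is re-sampled, and the probability that it ever
leaves the field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .sicm_model import InvalidParameterError

__all__ = [
    "LineageParams",
    "CellTrack",
    "LineageOutcome",
    "RecaptureEstimate",
    "simulate_lineage",
    "migration_stats",
    "recapture_probability",
]


@dataclass(frozen=True)
class LineageParams:
    """Migration / division / death model over a bounded field of view.

    Units: micrometres and hours.  Defaults describe the longitudinal
    experiment: a 1300 x 1300 um field of view, a 72-h course, a ~24-h
    doubling time and a post-biopsy death rate giving ~20% lineage
    survival at 72 h; the migration scale keeps the chance of leaving
    the field of view at the ~2% level.

    ``forced_division_rounds`` replaces stochastic division with
    synchronous divisions of every cell at evenly spaced times (used to
    study the k-rounds -> 2^k progeny limit).
    """

    fov: tuple = (1300.0, 1300.0)
    duration: float = 72.0
    step_interval: float = 2.0
    speed_scale: float = 35.0
    division_rate: float = math.log(2.0) / 24.0
    death_rate: float = 0.04
    max_progeny_tracked: int = 512
    forced_division_rounds: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fov) <= 0 or self.duration <= 0 or self.step_interval <= 0:
            raise InvalidParameterError("fov, duration and step_interval must be positive")
        if min(self.speed_scale, self.division_rate, self.death_rate) < 0:
            raise InvalidParameterError("rates and speed_scale must be >= 0")


@dataclass
class CellTrack:
    """One cell: parent link, lifetime and its recorded positions."""

    cell_id: int
    parent: Optional[int]
    birth_step: int
    positions: list  # (x, y) per step from birth while alive
    alive: bool = True


@dataclass
class LineageOutcome:
    """Result of one lineage simulation."""

    params: LineageParams
    cells: list  # CellTrack, founder first
    n_steps: int

    @property
    def founder(self) -> CellTrack:
        return self.cells[0]

    def final_positions(self, alive_only: bool = True) -> np.ndarray:
        pts = [c.positions[-1] for c in self.cells if c.alive or not alive_only]
        return np.array(pts) if pts else np.empty((0, 2))

    def in_fov(self, point) -> bool:
        hx, hy = self.params.fov[0] / 2.0, self.params.fov[1] / 2.0
        return abs(point[0]) <= hx and abs(point[1]) <= hy


def _step_vector(rng: np.random.Generator, scale: float) -> tuple:
    length = abs(rng.normal(0.0, scale)) if scale > 0 else 0.0
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return length * math.cos(theta), length * math.sin(theta)


def simulate_lineage(params: LineageParams, rng: Optional[np.random.Generator] = None) -> LineageOutcome:
    """Simulate one lineage from a founder at the field-of-view centre.

    Each time step every living cell takes a migration step; division and
    death compete as exponential clocks within the step (the dividing cell
    keeps its identity and spawns one daughter at its position).
    Reproducible for a fixed ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dt = params.step_interval
    n_steps = int(round(params.duration / dt))
    step_scale = params.speed_scale * dt

    forced_steps: set = set()
    if params.forced_division_rounds:
        k = params.forced_division_rounds
        forced_steps = {
            max(int(round(n_steps * (j + 1) / (k + 1))), 1) for j in range(k)
        }

    cells = [CellTrack(cell_id=0, parent=None, birth_step=0, positions=[(0.0, 0.0)])]
    lam, mu = params.division_rate, params.death_rate
    total_rate = lam + mu
    p_event = 1.0 - math.exp(-total_rate * dt) if total_rate > 0 else 0.0
    p_div_given_event = lam / total_rate if total_rate > 0 else 0.0

    for step in range(1, n_steps + 1):
        newborns = []
        for cell in cells:
            if not cell.alive:
                continue
            x, y = cell.positions[-1]
            dx, dy = _step_vector(rng, step_scale)
            pos = (x + dx, y + dy)
            cell.positions.append(pos)
            if params.forced_division_rounds:
                if step in forced_steps and len(cells) + len(newborns) < params.max_progeny_tracked:
                    newborns.append(
                        CellTrack(
                            cell_id=-1, parent=cell.cell_id, birth_step=step, positions=[pos]
                        )
                    )
            elif total_rate > 0 and rng.uniform() < p_event:
                if rng.uniform() < p_div_given_event:
                    if len(cells) + len(newborns) < params.max_progeny_tracked:
                        newborns.append(
                            CellTrack(
                                cell_id=-1, parent=cell.cell_id, birth_step=step, positions=[pos]
                            )
                        )
                else:
                    cell.alive = False
        for nb in newborns:
            nb.cell_id = len(cells)
            cells.append(nb)
    return LineageOutcome(params=params, cells=cells, n_steps=n_steps)


def migration_stats(outcome: LineageOutcome) -> dict:
    """Founder path length, lineage-wide maximum displacement and the
    bounding-box area of the final progeny positions.

    ``dx_tot``/``dx_max`` in micrometres, ``progeny_area`` in mm^2.
    """
    if not outcome.cells:
        raise InvalidParameterError("outcome has no cells")
    founder = np.array(outcome.founder.positions)
    steps = np.diff(founder, axis=0)
    dx_tot = float(np.hypot(steps[:, 0], steps[:, 1]).sum()) if len(steps) else 0.0
    dx_max = 0.0
    for cell in outcome.cells:
        pts = np.array(cell.positions)
        dx_max = max(dx_max, float(np.hypot(pts[:, 0], pts[:, 1]).max()))
    finals = outcome.final_positions(alive_only=True)
    if len(finals) == 0:
        area = 0.0
    else:
        span = finals.max(axis=0) - finals.min(axis=0)
        area = float(span[0] * span[1]) / 1e6  # um^2 -> mm^2
    return {"dx_tot": dx_tot, "dx_max": dx_max, "progeny_area": area}


@dataclass
class RecaptureEstimate:
    """Monte-Carlo recapture probabilities with a Wilson 95% CI."""

    p_out_of_fov: float
    p_recapture_original: float
    ci95: tuple
    n_reps: int
    n_no_survivors: int = 0


def recapture_probability(params: LineageParams, n_reps: int = 1000) -> RecaptureEstimate:
    """Probability that the day-4 biopsy samples the founder cell.

    Per replicate the biopsy picks uniformly among the surviving in-field
    lineage cells; replicates with no surviving in-field cell are excluded
    from the conditional denominator and reported separately.
    ``p_out_of_fov`` is the fraction of replicates in which the founder
    ever leaves the field of view.
    """
    if n_reps < 100:
        raise InvalidParameterError("n_reps must be >= 100")
    rng = np.random.default_rng(params.seed)
    founder_picked = 0
    reps_with_survivors = 0
    out_of_fov = 0
    hx, hy = params.fov[0] / 2.0, params.fov[1] / 2.0
    for _ in range(n_reps):
        outcome = simulate_lineage(params, rng=rng)
        fpts = np.array(outcome.founder.positions)
        if np.any((np.abs(fpts[:, 0]) > hx) | (np.abs(fpts[:, 1]) > hy)):
            out_of_fov += 1
        survivors = [
            c for c in outcome.cells if c.alive and outcome.in_fov(c.positions[-1])
        ]
        if not survivors:
            continue
        reps_with_survivors += 1
        pick = survivors[rng.integers(len(survivors))]
        if pick.cell_id == 0:
            founder_picked += 1
    if reps_with_survivors == 0:
        p_rec, ci = 0.0, (0.0, 1.0)
    else:
        p_rec = founder_picked / reps_with_survivors
        ci = proportion_confint(founder_picked, reps_with_survivors, alpha=0.05, method="wilson")
    return RecaptureEstimate(
        p_out_of_fov=out_of_fov / n_reps,
        p_recapture_original=p_rec,
        ci95=(float(ci[0]), float(ci[1])),
        n_reps=n_reps,
        n_no_survivors=n_reps - reps_with_survivors,
    )
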