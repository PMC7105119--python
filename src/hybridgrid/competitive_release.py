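"""Competitive-release hybrid tumor model: three treatment arms.

Two tumor-cell phenotypes compete on a 100x100 unstackable lattice: a
fast-dividing drug-SENSITIVE type and a slower drug-RESISTANT type.  A
diffusible drug enters through the domain boundary while treatment is on
(ADI diffusion with a Dirichlet boundary value), is consumed by every
cell, and adds to the death probability of sensitive cells only.  Each
two-hour tick every cell may die, then may divide into a random empty
Moore neighbor; daughters inherit the phenotype.

The experiment runs three identically seeded copies of the model that
differ only in the treatment window length: no drug at all, effectively
constant drug (window longer than the dosing period), and pulsed drug.
Pulsed therapy keeps the sensitive population in check while it still
competes spatially with — and thereby suppresses — the resistant clone:
competitive release in silico.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

from .agents import Agent, AgentGrid
from .lattice import circle_hood, map_hood, moore_hood
from .output import DelimitedWriter
from .pde import PDEField
from .raster import GifMaker, Raster
from .rng import RandomSource
from .toolkit import heat_map_rgb, prob_scale, rgb

RESISTANT = rgb(0, 1, 0)   # green
SENSITIVE = rgb(0, 0, 1)   # blue

ARM_NAMES = ("no_drug", "constant", "pulsed")


@dataclass
class CompetitiveReleaseParams:
    """Every constant of the worked example.

    Probabilities are quoted per day and rescaled to per-tick values with
    ``prob_scale`` so the expected number of events per day is preserved.
    The drug diffusivity 0.02 um^2/s is converted to lattice units
    (20 um spacing, 2 h ticks), giving the dimensionless ADI rate 0.36 —
    above the 0.25 explicit 2D stability bound, which is why the model
    uses ADI.
    """

    timestep: float = 2.0 / 24          # days per tick (2 hours)
    space_step: float = 20.0            # um per lattice unit (cell diameter)
    xDim: int = 100
    yDim: int = 100
    tumorRad: float = 10.0              # initial tumor radius, lattice units
    resistantProb: float = 0.5
    steps: int = 10000
    seed: int = 0
    div_rate_sen: float = 0.5           # per-day division probability
    div_rate_res: float = 0.2
    death_rate: float = 0.02            # per-day baseline death probability
    drug_death_rate: float = 0.8        # per-day at unit drug concentration
    drug_uptake_per_day: float = -0.03  # fractional uptake per cell per day
    drug_diffusivity: float = 0.02      # um^2 / s
    drug_boundary_val: float = 1.0

    # derived per-tick constants, filled in __post_init__
    div_prob_sen: float = field(init=False)
    div_prob_res: float = field(init=False)
    death_prob: float = field(init=False)
    drug_death: float = field(init=False)
    drug_start: float = field(init=False)     # ticks
    drug_period: float = field(init=False)    # ticks
    drug_duration: float = field(init=False)  # ticks (pulsed default)
    drug_uptake: float = field(init=False)
    drug_diff_rate: float = field(init=False)

    def __post_init__(self):
        ts = self.timestep
        self.div_prob_sen = prob_scale(self.div_rate_sen, ts)
        self.div_prob_res = prob_scale(self.div_rate_res, ts)
        self.death_prob = prob_scale(self.death_rate, ts)
        self.drug_death = prob_scale(self.drug_death_rate, ts)
        self.drug_start = 20.0 / ts       # treatment begins day 20
        self.drug_period = 15.0 / ts      # dosing cycle: 15 days
        self.drug_duration = 2.0 / ts     # pulsed window: 2 days
        self.drug_uptake = self.drug_uptake_per_day * ts
        self.drug_diff_rate = (self.drug_diffusivity * 60 * 60 * 24
                               * ts / (self.space_step * self.space_step))

    @property
    def domain_area_mm2(self) -> float:
        """Physical domain area in mm^2."""
        side_x = self.xDim * self.space_step / 1000.0
        side_y = self.yDim * self.space_step / 1000.0
        return side_x * side_y

    @property
    def simulated_days(self) -> float:
        return self.steps * self.timestep

    @property
    def simulated_years(self) -> float:
        return self.simulated_days / 365.0

    def arm_duration(self, arm: str) -> float:
        """Treatment window (ticks) for a named arm.

        ``no_drug`` never doses; ``constant`` uses a 200-tick window,
        longer than the 180-tick period, so dosing is effectively
        uninterrupted; ``pulsed`` uses the 2-day default window.
        """
        if arm == "no_drug":
            return 0.0
        if arm == "constant":
            return 200.0
        if arm == "pulsed":
            return self.drug_duration
        raise ValueError(f"unknown arm {arm!r}")


class Cell(Agent):
    """Tumor cell; ``type`` is SENSITIVE or RESISTANT (packed color)."""

    def __init__(self):
        super().__init__()
        self.type = SENSITIVE


class CompetitiveReleaseModel:
    """One treatment arm: agent lattice + drug PDE field + rng."""

    def __init__(self, params: CompetitiveReleaseParams, rng: RandomSource,
                 drug_duration: float | None = None):
        self.params = params
        self.rng = rng
        self.grid = AgentGrid(params.xDim, params.yDim, Cell, stackable=False)
        self.drug = PDEField(params.xDim, params.yDim)
        self.divHood = moore_hood(False)
        self.drug_duration = (params.drug_duration if drug_duration is None
                              else drug_duration)

    # -- setup -------------------------------------------------------------
    def init_tumor(self, radius: float | None = None,
                   resistantProb: float | None = None) -> int:
        """Seed a filled circle of cells at the grid center.

        Each position within ``radius`` of the center receives one cell,
        resistant with probability ``resistantProb`` (one rng draw per
        cell, in neighborhood order).  Returns the number created.
        """
        p = self.params
        radius = p.tumorRad if radius is None else radius
        resistantProb = p.resistantProb if resistantProb is None else resistantProb
        hood = circle_hood(True, radius)
        n = map_hood(hood, p.xDim // 2, p.yDim // 2, self.grid.shape)
        for k in range(n):
            cell = self.grid.new_agent_sq(hood.indexBuffer[k])
            cell.type = RESISTANT if self.rng.next_double() < resistantProb else SENSITIVE
        return n

    # -- per-tick dynamics ---------------------------------------------------
    def cell_step(self, cell: Cell) -> None:
        """One cell's tick: drug uptake, death draw, division draw.

        The rng draw order (death, division, neighbor choice) is fixed so
        seeded runs are exactly reproducible.
        """
        p = self.params
        drug = self.drug
        i = cell.i
        drug._dflat[i] += drug._vflat[i] * p.drug_uptake
        if cell.type == RESISTANT:
            deathProb = p.death_prob
        else:
            deathProb = p.death_prob + drug._vflat[i] * p.drug_death
        if self.rng.next_double() < deathProb:
            self.grid.dispose(cell)
            return
        divProb = p.div_prob_res if cell.type == RESISTANT else p.div_prob_sen
        if self.rng.next_double() < divProb:
            options = self.grid.map_empty_hood(self.divHood, cell)
            if options > 0:
                daughter = self.grid.new_agent_sq(
                    self.divHood.indexBuffer[self.rng.next_int(options)])
                daughter.type = cell.type

    def drug_on(self, tick: int) -> bool:
        """Is the treatment window open at this tick?

        True iff ``tick > drug_start`` and the truncated remainder of
        ``tick - drug_start`` by the dosing period lies strictly inside
        (0, drug_duration).  The explicit guard keeps ticks before the
        treatment start unambiguously drug-free.
        """
        p = self.params
        if tick <= p.drug_start:
            return False
        periodTick = math.fmod(tick - p.drug_start, p.drug_period)
        return 0 < periodTick < self.drug_duration

    def model_step(self, tick: int) -> None:
        """One model tick: shuffle, step every cell, diffuse drug, commit.

        The cell sweep is an inlined copy of :meth:`cell_step` with all
        lookups hoisted out of the loop — drawing from the rng in exactly
        the same order, so both paths produce identical trajectories (a
        regression test holds them together).
        """
        p = self.params
        grid = self.grid
        rng = self.rng
        grid.shuffle_agents(rng)
        nd = rng.next_double
        ni = rng.next_int
        drug = self.drug
        vf, df = drug._vflat, drug._dflat
        uptake, base_death = p.drug_uptake, p.death_prob
        drug_death = p.drug_death
        div_res, div_sen = p.div_prob_res, p.div_prob_sen
        dispose, new_sq = grid.dispose, grid.new_agent_sq
        meh, hood = grid.map_empty_hood, self.divHood
        buf = hood.indexBuffer
        RES = RESISTANT
        lst = grid._list
        n = len(lst)
        grid._active_sweeps += 1
        try:
            for k in range(n):
                cell = lst[k]
                if cell is None:
                    continue
                i = cell.i
                df[i] += vf[i] * uptake
                if cell.type == RES:
                    if nd() < base_death:
                        dispose(cell)
                        continue
                    divProb = div_res
                else:
                    if nd() < base_death + vf[i] * drug_death:
                        dispose(cell)
                        continue
                    divProb = div_sen
                if nd() < divProb:
                    options = meh(hood, cell)
                    if options > 0:
                        new_sq(buf[ni(options)]).type = cell.type
        finally:
            grid._active_sweeps -= 1
        if self.drug_on(tick):
            # drug enters through the boundaries
            self.drug.diffusion_adi(p.drug_diff_rate, p.drug_boundary_val)
        else:
            # closed boundaries: uptake is the only sink
            self.drug.diffusion_adi(p.drug_diff_rate)
        self.drug.update()
        grid.increment_tick()

    # -- observables ---------------------------------------------------------
    def population(self) -> int:
        return self.grid.population()

    def type_counts(self) -> tuple:
        """(sensitive, resistant) live-cell counts."""
        nres = sum(1 for c in self.grid if c.type == RESISTANT)
        return self.grid.population() - nres, nres

    def draw_model(self, raster: Raster, slot: int = 0) -> None:
        """Render this model into horizontal slot ``slot`` of a raster.

        Cells draw as their phenotype color; empty squares show the drug
        concentration through the heat colormap.
        """
        p = self.params
        if raster.width < (slot + 1) * p.xDim:
            raise IndexError("raster too narrow for this slot")
        get_agent = self.grid.get_agent
        vflat = self.drug._vflat
        yDim = p.yDim
        x0 = slot * p.xDim
        for x in range(p.xDim):
            base = x * yDim
            for y in range(yDim):
                cell = get_agent(base + y)
                if cell is not None:
                    raster.set_pix(x0 + x, y, cell.type)
                else:
                    raster.set_pix(x0 + x, y, heat_map_rgb(vflat[base + y]))


def build_arms(params: CompetitiveReleaseParams,
               arms=ARM_NAMES) -> list:
    """Three identically seeded, identically initialized models."""
    models = []
    for arm in arms:
        m = CompetitiveReleaseModel(params, RandomSource(params.seed),
                                    drug_duration=params.arm_duration(arm))
        m.init_tumor()
        models.append(m)
    return models


def run_experiment(params: CompetitiveReleaseParams, outDir,
                   arms=ARM_NAMES, snapshot_days: float = 10.0,
                   visScale: int = 5, make_gif: bool = False) -> dict:
    """Run the three-arm experiment, writing CSV and PNG snapshots.

    Emits one ``populations.csv`` row per tick (one column per arm, no
    header) and a side-by-side raster PNG named ``ModelsDay<d>.png``
    every ``snapshot_days`` simulated days.  Returns paths and models.
    """
    os.makedirs(outDir, exist_ok=True)
    models = build_arms(params, arms)
    raster = Raster(params.xDim * len(models), params.yDim, visScale)
    gif = GifMaker() if make_gif else None
    csv_path = os.path.join(outDir, "populations.csv")
    pops_out = DelimitedWriter(csv_path)
    snap_every = max(1, int(round(snapshot_days / params.timestep)))
    pngs = []
    for tick in range(params.steps):
        for m in models:
            m.model_step(tick)
        pops_out.write(",".join(str(m.population()) for m in models) + "\n")
        if tick % snap_every == 0:
            for slot, m in enumerate(models):
                m.draw_model(raster, slot)
            day = int(tick * params.timestep)
            png = os.path.join(outDir, f"ModelsDay{day}.png")
            raster.to_png(png)
            pngs.append(png)
            if gif is not None:
                gif.gif_add_frame(raster)
    pops_out.close()
    if gif is not None:
        gif.gif_save(os.path.join(outDir, "Models.gif"))
    return {"csv": csv_path, "pngs": pngs, "models": models}


def run_arm_statistics(params: CompetitiveReleaseParams, arms=ARM_NAMES,
                       occupancy_fraction: float = 0.9) -> dict:
    """Run all arms without file output and collect summary statistics.

    For each arm: total population and resistant fraction at the final
    tick, plus the first tick at which the lattice is
    ``occupancy_fraction`` full (None if never).
    """
    models = build_arms(params, arms)
    threshold = occupancy_fraction * params.xDim * params.yDim
    first_full = {arm: None for arm in arms}
    for tick in range(params.steps):
        for arm, m in zip(arms, models):
            m.model_step(tick)
            if first_full[arm] is None and m.population() >= threshold:
                first_full[arm] = tick
    out = {}
    for arm, m in zip(arms, models):
        nsen, nres = m.type_counts()
        pop = m.population()
        out[arm] = {
            "population": pop,
            "resistant_fraction": nres / pop if pop else 0.0,
            "first_full_tick": first_full[arm],
        }
    return out
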