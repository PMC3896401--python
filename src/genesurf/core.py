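"""Individual-based lattice simulations of gene surfing at range-expansion fronts.

The model evolves a haploid, asexual population carrying one neutral diallelic
locus on a rectangular lattice of demes (stepping-stone migration, carrying
capacity ``K`` per deme).  Each generation is reproduction (Poisson offspring
with mean ``r`` per individual), migration (each individual leaves its deme
with probability ``m``, destination uniform over the orthogonally adjacent
demes), then culling (uniform random removal down to ``K`` wherever a deme
exceeds it).  Range expansion proceeds left to right; whenever a previously
unoccupied column first has every deme at ``K`` its allele frequencies are
captured as a *frozen record* — the permanent genetic signature left by the
passing front.

Three habitat scenarios are supported:

* ``PhLRE`` (phenotype-limited range expansion): the whole lattice is suitable
  from the start; expansion speed is set by ``r`` and ``m``.
* ``BLRE`` (boundary-limited range expansion): only the first columns are
  suitable initially and the habitat opens column by column over a fixed
  number of generations; expansion speed is set by the boundary.
* ``stationary``: the habitat never grows; the last suitable column is the
  "stationary front", the zero-expansion-speed reference.

The analysis layer summarises each frozen column by run-length segmentation
into genetically homogeneous domains (runs of demes fixed for one allele) and
allele-frequency clines (runs of mixed demes), mean pairwise differences
within demes (PX), between demes (PXY) and corrected between demes
(Pc = PXY − (PX+PY)/2), and the amplitude-weighted mean spatial frequency of
the column's allele-frequency profile (``fbar``).

The file is organised in the order the method runs: configuration and
parameters, habitat schedule, simulator, front statistics, experiment runner.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "HabitatSchedule",
    "LatticeState",
    "FrozenRecord",
    "RunResult",
    "build_schedule",
    "init_state",
    "reproduce",
    "migrate",
    "cull",
    "step",
    "run",
    "SegmentationResult",
    "FrontStatRow",
    "segment_column",
    "fbar",
    "pairwise_within",
    "pairwise_between",
    "pairwise_corrected",
    "front_stats",
    "records_to_frame",
    "stats_frame",
    "SweepSpec",
    "AveragedTrajectory",
    "run_sweep",
    "preset",
    "PRESET_NAMES",
    "load_params",
    "plot_record_heatmap",
]

# --------------------------------------------------------------------------
# Configuration & logging
# --------------------------------------------------------------------------

logger = logging.getLogger("genesurf")

SCENARIOS = ("PhLRE", "BLRE", "stationary")

#: Lattice and life-history defaults of the reference simulation study.
DEFAULT_N_ROWS = 75
DEFAULT_N_COLS = 200
DEFAULT_K = 100
DEFAULT_R = 3.0
DEFAULT_M = 0.2
DEFAULT_P0 = 0.5
DEFAULT_N_INIT_COLS = 20
DEFAULT_MAX_GENERATIONS = 8000

#: Boundary-motion durations (generations for the whole habitat to open).
#: The reference experiments circulate with two slightly different lists
#: (800 replacing 600 in one of them).  Both are shipped; see ``preset``.
BLRE_DURATIONS_METHODS = (600, 1000, 2000, 4000, 6000, 7900)
BLRE_DURATIONS_CAPTION = (800, 1000, 2000, 4000, 6000, 7900)


def _canonical_scenario(name: str) -> str:
    for s in SCENARIOS:
        if name.lower() == s.lower():
            return s
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


# --------------------------------------------------------------------------
# Parameters & domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Complete parameterisation of one simulation replicate.

    Parameters
    ----------
    n_rows
        Lattice rows (demes per column, orthogonal to the expansion axis).
        Must be odd: the spectrum statistic indexes harmonics up to
        ``(n_rows - 1) / 2``.
    n_cols
        Lattice columns along the expansion axis.
    K
        Carrying capacity per deme (individuals).
    r
        Mean Poisson offspring number per individual per generation.
    m
        Per-individual emigration probability per generation, in [0, 1].
    p0
        Initial frequency of allele A in the founding columns.
    n_init_cols
        Number of leftmost columns populated (at size ``K``) at generation 0.
    max_generations
        Hard stop for the generation loop.
    scenario
        ``"PhLRE"``, ``"BLRE"`` or ``"stationary"``.
    boundary_duration
        BLRE only: generations for the habitat to open completely.
    seed
        Seed for the replicate's single random generator.
    snapshot_generations
        Stationary scenario only: generations at which the stationary-front
        column (column ``n_init_cols``, 1-based) is snapshot as a frozen
        record.  Defaults to ``(max_generations,)``.
    stop_after_complete
        Stop the generation loop once every column beyond the initial block
        has a frozen record (records and expansion time are unaffected).
    """

    n_rows: int = DEFAULT_N_ROWS
    n_cols: int = DEFAULT_N_COLS
    K: int = DEFAULT_K
    r: float = DEFAULT_R
    m: float = DEFAULT_M
    p0: float = DEFAULT_P0
    n_init_cols: int = DEFAULT_N_INIT_COLS
    max_generations: int = DEFAULT_MAX_GENERATIONS
    scenario: str = "PhLRE"
    boundary_duration: int | None = None
    seed: int = 0
    snapshot_generations: tuple[int, ...] | None = None
    stop_after_complete: bool = True
    migration_model: str = "m-over-n"

    def __post_init__(self):
        object.__setattr__(self, "scenario", _canonical_scenario(self.scenario))
        if self.n_rows < 1 or self.n_rows % 2 == 0:
            raise ValueError("n_rows must be odd and >= 1")
        if self.n_cols < 1:
            raise ValueError("n_cols must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must be in [0, 1]")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if not 1 <= self.n_init_cols <= self.n_cols:
            raise ValueError("n_init_cols must be in [1, n_cols]")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")
        if self.scenario == "BLRE":
            if self.boundary_duration is None or self.boundary_duration < 1:
                raise ValueError("BLRE requires boundary_duration >= 1")
        if self.migration_model not in MIGRATION_MODELS:
            raise ValueError(f"migration_model must be one of {MIGRATION_MODELS}")

    @property
    def init_nA(self) -> int:
        """Founding per-deme count of allele A: p0*K rounded half up."""
        exact = self.p0 * self.K
        rounded = int(math.floor(exact + 0.5))
        if abs(exact - rounded) > 1e-9:
            logger.warning(
                "p0*K = %s is not an integer; rounding founding allele-A count to %d",
                exact, rounded,
            )
        return rounded


@dataclass(frozen=True)
class HabitatSchedule:
    """Maps generation number to the count of suitable columns (left block).

    The habitat is always a contiguous left-anchored block of columns; the
    suitable-column count is non-decreasing in the generation.
    """

    scenario: str
    n_cols: int
    n_init_cols: int
    boundary_duration: int | None = None

    def n_suitable(self, generation: int) -> int:
        if self.scenario == "PhLRE":
            return self.n_cols
        if self.scenario == "stationary":
            return self.n_init_cols
        # BLRE: columns open at evenly spaced generations.
        opened = (self.n_cols - self.n_init_cols) * generation // self.boundary_duration
        return min(self.n_init_cols + max(opened, 0), self.n_cols)

    def suitable_mask(self, generation: int) -> np.ndarray:
        """Boolean mask over columns, True where habitat is suitable."""
        mask = np.zeros(self.n_cols, dtype=bool)
        mask[: self.n_suitable(generation)] = True
        return mask


@dataclass
class LatticeState:
    """Evolving simulator state: per-deme allele counts and suitability.

    ``nA``/``na`` are (n_rows, n_cols) integer arrays of allele counts;
    ``suitable`` is a per-column boolean mask (habitat is column-structured).
    """

    nA: np.ndarray
    na: np.ndarray
    suitable: np.ndarray
    generation: int = 0

    @property
    def n_rows(self) -> int:
        return self.nA.shape[0]

    @property
    def n_cols(self) -> int:
        return self.nA.shape[1]

    @property
    def total(self) -> np.ndarray:
        return self.nA + self.na

    def global_frequency(self) -> float:
        """Frequency of allele A over the whole lattice (nan if empty)."""
        tot = int(self.nA.sum() + self.na.sum())
        if tot == 0:
            return float("nan")
        return float(self.nA.sum() / tot)

    def occupied_columns(self) -> int:
        return int((self.total.sum(axis=0) > 0).sum())


@dataclass(frozen=True)
class FrozenRecord:
    """Allele-frequency snapshot of one column at the moment it filled to K.

    ``column_index`` is 1-based, matching the convention "the first 20
    columns".  ``nA`` holds the integer allele-A counts (each deme at size K),
    so ``frequencies`` are exact multiples of 1/K.
    """

    column_index: int
    generation_recorded: int
    nA: np.ndarray
    K: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.nA / self.K


@dataclass
class RunResult:
    """Outcome of a single replicate."""

    records: list[FrozenRecord]
    final_state: LatticeState
    expansion_time: int | None

    def __iter__(self):  # tuple-style unpacking
        return iter((self.records, self.final_state, self.expansion_time))


# --------------------------------------------------------------------------
# Habitat schedule & initial state
# --------------------------------------------------------------------------


def build_schedule(params: SimParams) -> HabitatSchedule:
    """Build the habitat schedule for the given scenario.

    PhLRE: all columns suitable from generation 0.  Stationary: the initial
    block only, forever.  BLRE: the block grows linearly, reaching the full
    lattice at ``boundary_duration`` generations.
    """
    return HabitatSchedule(
        scenario=params.scenario,
        n_cols=params.n_cols,
        n_init_cols=params.n_init_cols,
        boundary_duration=params.boundary_duration,
    )


def init_state(params: SimParams) -> LatticeState:
    """Founding lattice: first ``n_init_cols`` columns at size K, frequency p0."""
    shape = (params.n_rows, params.n_cols)
    nA = np.zeros(shape, dtype=np.int64)
    na = np.zeros(shape, dtype=np.int64)
    kA = params.init_nA
    nA[:, : params.n_init_cols] = kA
    na[:, : params.n_init_cols] = params.K - kA
    suitable = build_schedule(params).suitable_mask(0)
    return LatticeState(nA=nA, na=na, suitable=suitable, generation=0)


# --------------------------------------------------------------------------
# Simulator: reproduction -> migration -> culling
# --------------------------------------------------------------------------


def reproduce(state: LatticeState, r: float, rng: np.random.Generator) -> LatticeState:
    """Replace every parent by a Poisson number of offspring (in place).

    In suitable demes each allele's count becomes Poisson(r * count) — the sum
    of independent per-individual Poisson(r) draws.  In unsuitable habitat the
    effective reproduction rate is 0, so occupants leave no offspring; parents
    die everywhere after reproducing.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    suit = state.suitable[np.newaxis, :]
    state.nA = rng.poisson(np.where(suit, r * state.nA, 0.0)).astype(np.int64)
    state.na = rng.poisson(np.where(suit, r * state.na, 0.0)).astype(np.int64)
    return state


@lru_cache(maxsize=8)
def _direction_layout(n_rows: int, n_cols: int):
    """Per-cell valid movement directions (up, down, left, right) and the
    count of valid directions from each index onward, for the sequential
    uniform split of migrants.  Edge and corner demes have 3 and 2 neighbours
    (no wrap-around)."""
    valid = np.ones((4, n_rows, n_cols), dtype=bool)
    valid[0, 0, :] = False           # no deme above the top row
    valid[1, n_rows - 1, :] = False  # none below the bottom row
    valid[2, :, 0] = False           # none left of the first column
    valid[3, :, n_cols - 1] = False  # none right of the last column
    remaining = np.cumsum(valid[::-1].astype(np.int64), axis=0)[::-1]
    return valid, remaining


#: Emigration conventions.  ``"m-over-n"`` (default): an individual in a deme
#: with n adjacent demes leaves with probability m/n; this is the reading of
#: the migration formula that reproduces the reference pilot expansion time.
#: ``"m"``: every individual leaves with probability m regardless of position.
#: Destination is uniform over the n adjacent demes in both conventions.
MIGRATION_MODELS = ("m-over-n", "m")
DEFAULT_MIGRATION_MODEL = "m-over-n"


def _scatter_counts(counts: np.ndarray, m, valid: np.ndarray,
                    remaining: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial migration of one allele's counts: each individual leaves
    with probability ``m`` (scalar or per-cell array), and conditional on
    leaving moves to one of its valid neighbours uniformly.  Exactly
    conserves the total count."""
    leavers = rng.binomial(counts, m)
    new = counts - leavers
    # Uniform partition over valid directions via sequential conditional
    # binomials: the d-th draw takes a 1/(#valid directions from d on) share.
    rem = leavers
    moved = []
    for d in range(4):
        n_d = np.where(valid[d], rem, 0)
        p_d = 1.0 / np.maximum(remaining[d], 1)
        c = rng.binomial(n_d, p_d)
        rem = rem - c
        moved.append(c)
    new[:-1, :] += moved[0][1:, :]   # up-movers land one row above
    new[1:, :] += moved[1][:-1, :]   # down
    new[:, :-1] += moved[2][:, 1:]   # left
    new[:, 1:] += moved[3][:, :-1]   # right
    return new


def _leave_probability(m: float, remaining: np.ndarray, model: str):
    """Per-cell emigration probability under the chosen convention."""
    n_neighbours = remaining[0]
    isolated = n_neighbours == 0  # a 1x1 lattice has nowhere to go
    if model == "m-over-n":
        return np.where(isolated, 0.0, m / np.maximum(n_neighbours, 1))
    if model == "m":
        return np.where(isolated, 0.0, m)
    raise ValueError(f"unknown migration model {model!r}; "
                     f"expected one of {MIGRATION_MODELS}")


def migrate(state: LatticeState, m: float, rng: np.random.Generator,
            model: str = DEFAULT_MIGRATION_MODEL) -> LatticeState:
    """Stepping-stone migration to orthogonally adjacent demes (in place).

    Under the default convention each individual emigrates with probability
    m/n, where n is the number of demes orthogonally adjacent to its own
    (2 at corners, 3 at edges, 4 in the interior; no wrap-around), and its
    destination is uniform over those n.  ``model="m"`` instead makes the
    emigration probability m everywhere.  Movement is blind to habitat
    suitability: migrants may enter unsuitable demes, where they will die at
    the next reproduction step.  The lattice total is conserved exactly.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must be in [0, 1]")
    if m == 0.0:
        return state
    valid, remaining = _direction_layout(state.n_rows, state.n_cols)
    p_leave = _leave_probability(m, remaining, model)
    state.nA = _scatter_counts(state.nA, p_leave, valid, remaining, rng)
    state.na = _scatter_counts(state.na, p_leave, valid, remaining, rng)
    return state


def cull(state: LatticeState, K: int, rng: np.random.Generator) -> LatticeState:
    """Randomly remove individuals down to K wherever a deme exceeds it.

    Retention is uniform sampling without replacement, so the retained
    allele-A count is hypergeometric; demes at or below K are untouched.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    total = state.nA + state.na
    over = total > K
    if over.any():
        kept_A = rng.hypergeometric(state.nA[over], state.na[over], K)
        state.nA[over] = kept_A
        state.na[over] = K - kept_A
    return state


def step(state: LatticeState, params: SimParams, schedule: HabitatSchedule,
         rng: np.random.Generator) -> LatticeState:
    """Advance one generation: update suitability, then reproduce → migrate →
    cull, and increment the generation counter."""
    gen = state.generation + 1
    state.suitable = schedule.suitable_mask(gen)
    reproduce(state, params.r, rng)
    migrate(state, params.m, rng, model=params.migration_model)
    cull(state, params.K, rng)
    state.generation = gen
    return state


def _active_window(state: LatticeState) -> int:
    """Rightmost column that can be affected next generation (exclusive
    upper bound): one past the last occupied column."""
    occupied = np.flatnonzero((state.nA + state.na).sum(axis=0) > 0)
    if occupied.size == 0:
        return 0
    return min(int(occupied[-1]) + 2, state.n_cols)


def _step_windowed(state: LatticeState, params: SimParams,
                   schedule: HabitatSchedule, rng: np.random.Generator) -> None:
    """One generation restricted to the occupied column window.

    Columns right of the window are empty and unreachable this generation, so
    skipping them is exact; direction layouts are sliced from the full-lattice
    layout so edge demes keep their true neighbour counts.
    """
    gen = state.generation + 1
    state.suitable = schedule.suitable_mask(gen)
    w = _active_window(state)
    if w > 0:
        nA = state.nA[:, :w]
        na = state.na[:, :w]
        suit = state.suitable[np.newaxis, :w]
        nA = rng.poisson(np.where(suit, params.r * nA, 0.0)).astype(np.int64)
        na = rng.poisson(np.where(suit, params.r * na, 0.0)).astype(np.int64)
        if params.m > 0.0:
            valid, remaining = _direction_layout(state.n_rows, state.n_cols)
            vw, rw = valid[:, :, :w], remaining[:, :, :w]
            p_leave = _leave_probability(params.m, rw, params.migration_model)
            nA = _scatter_counts(nA, p_leave, vw, rw, rng)
            na = _scatter_counts(na, p_leave, vw, rw, rng)
        total = nA + na
        over = total > params.K
        if over.any():
            kept = rng.hypergeometric(nA[over], na[over], params.K)
            nA[over] = kept
            na[over] = params.K - kept
        state.nA[:, :w] = nA
        state.na[:, :w] = na
    state.generation = gen


def run(params: SimParams, rng: np.random.Generator | None = None) -> RunResult:
    """Run one replicate and collect frozen records.

    After each generation, any not-yet-recorded column beyond the initial
    block whose demes are all exactly at K is frozen (its allele-A
    frequencies captured).  ``expansion_time`` is the first generation at
    which every such column has been recorded; ``None`` if the lattice never
    fills within ``max_generations``.  In the stationary scenario the habitat
    never grows, so instead the stationary-front column (the last suitable
    one) is snapshot at ``params.snapshot_generations``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    schedule = build_schedule(params)
    state = init_state(params)
    records: list[FrozenRecord] = []
    expansion_time: int | None = None

    stationary = params.scenario == "stationary"
    snapshot_gens = set(params.snapshot_generations or ((params.max_generations,) if stationary else ()))
    recorded = np.zeros(params.n_cols, dtype=bool)
    recorded[: params.n_init_cols] = True  # initial block is never frozen
    n_pending = params.n_cols - params.n_init_cols

    log_every = max(1, params.max_generations // 20)
    for _ in range(params.max_generations):
        _step_windowed(state, params, schedule, rng)
        gen = state.generation
        if stationary:
            if gen in snapshot_gens:
                j = params.n_init_cols - 1
                records.append(FrozenRecord(
                    column_index=params.n_init_cols,
                    generation_recorded=gen,
                    nA=state.nA[:, j].copy(),
                    K=params.K,
                ))
        else:
            full_cols = ((state.nA + state.na) == params.K).all(axis=0)
            new = np.flatnonzero(full_cols & ~recorded)
            for j in new:
                records.append(FrozenRecord(
                    column_index=int(j) + 1,
                    generation_recorded=gen,
                    nA=state.nA[:, j].copy(),
                    K=params.K,
                ))
            recorded[new] = True
            n_pending -= new.size
            if n_pending == 0 and expansion_time is None:
                expansion_time = gen
                if params.stop_after_complete:
                    break
        if logger.isEnabledFor(logging.DEBUG) and gen % log_every == 0:
            logger.debug(
                "gen %d: %d occupied columns, %d individuals",
                gen, state.occupied_columns(), int((state.nA + state.na).sum()),
            )
    return RunResult(records=records, final_state=state, expansion_time=expansion_time)


# --------------------------------------------------------------------------
# Front statistics: segmentation, spectrum, pairwise differences
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationResult:
    """Run-length decomposition of one column into homogeneous domains and
    clines.  ``domains`` holds (allele, start_row, width) with 1-based start
    rows; ``clines`` holds (start_row, width).  Mean widths are ``None`` when
    the corresponding segment class is absent."""

    domains: tuple[tuple[str, int, int], ...]
    clines: tuple[tuple[int, int], ...]

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_clines(self) -> int:
        return len(self.clines)

    @property
    def mean_domain_width(self) -> float | None:
        if not self.domains:
            return None
        return float(np.mean([w for _, _, w in self.domains]))

    @property
    def mean_cline_width(self) -> float | None:
        if not self.clines:
            return None
        return float(np.mean([w for _, w in self.clines]))


def segment_column(frequencies: Sequence[float], *, atol: float = 0.0) -> SegmentationResult:
    """Segment a column's allele-frequency profile into domains and clines.

    A deme is homogeneous when it is fixed for one allele (frequency exactly
    1 for A or 0 for a; counts are integers so exact fixation is
    well-defined).  A *domain* is a maximal run of demes fixed for the same
    allele — adjacent runs fixed for opposite alleles are distinct domains
    with no cline between them.  A *cline* is a maximal run of mixed demes.
    ``atol`` optionally relaxes fixation to within ``atol`` of 0 or 1.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise ValueError("empty column")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    # 0 = fixed a, 1 = fixed A, 2 = mixed
    label = np.full(p.size, 2, dtype=np.int8)
    label[p >= 1.0 - atol] = 1
    label[p <= atol] = 0
    boundaries = np.flatnonzero(np.diff(label)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [p.size]))
    domains = []
    clines = []
    for s, e in zip(starts, ends):
        lab = label[s]
        if lab == 2:
            clines.append((int(s) + 1, int(e - s)))
        else:
            domains.append(("A" if lab == 1 else "a", int(s) + 1, int(e - s)))
    return SegmentationResult(domains=tuple(domains), clines=tuple(clines))


def fbar(frequencies: Sequence[float]) -> float:
    """Amplitude-weighted mean spatial frequency of a column profile.

    With DFT coefficients P_k of the length-N profile (N odd), amplitudes
    A_k = |P_k| for harmonics k = 1 … (N−1)/2 (DC excluded) and frequencies
    f_k = k/N cycles per deme, returns Σ f_k A_k / Σ A_k.  A constant profile
    has an empty spectrum and returns 0 by convention.  Higher values mean
    finer-scale allele-frequency fluctuation along the column.
    """
    p = np.asarray(frequencies, dtype=float)
    n = p.size
    if n % 2 == 0:
        raise ValueError("profile length must be odd")
    if np.ptp(p) == 0.0:
        return 0.0
    amp = np.abs(np.fft.rfft(p)[1:])  # k = 1 .. (N-1)/2
    k = np.arange(1, n // 2 + 1)
    return float((k * amp).sum() / (n * amp.sum()))


def pairwise_within(nA: int, na: int) -> float:
    """Mean pairwise difference within a deme (PX) at one diallelic locus.

    Averaging the 0/1 difference over all C(n, 2) unordered pairs of the
    deme's n = nA + na individuals gives 2·nA·na / (n(n−1))."""
    n = nA + na
    if n < 2:
        raise ValueError("pairwise_within needs at least 2 individuals")
    return 2.0 * nA * na / (n * (n - 1))


def pairwise_between(demeX: tuple[int, int], demeY: tuple[int, int]) -> float:
    """Mean pairwise difference between two demes (PXY): the probability a
    random individual from each differs, pX(1−pY) + pY(1−pX)."""
    nAx, nax = demeX
    nAy, nay = demeY
    if nAx + nax == 0 or nAy + nay == 0:
        raise ValueError("pairwise_between needs non-empty demes")
    px = nAx / (nAx + nax)
    py = nAy / (nAy + nay)
    return px * (1.0 - py) + py * (1.0 - px)


def pairwise_corrected(demeX: tuple[int, int], demeY: tuple[int, int]) -> float:
    """Corrected between-deme pairwise difference Pc = PXY − (PX + PY)/2,
    the net divergence after removing mean within-deme diversity."""
    px_within = pairwise_within(*demeX)
    py_within = pairwise_within(*demeY)
    return pairwise_between(demeX, demeY) - (px_within + py_within) / 2.0


@dataclass(frozen=True)
class FrontStatRow:
    """Per-column spatial-genetic summary of a frozen record."""

    n_domains: int
    n_clines: int
    mean_domain_width: float | None
    mean_cline_width: float | None
    PX: float
    PXY: float
    Pc: float
    fbar: float


def front_stats(nA: Sequence[int], na: Sequence[int], *, atol: float = 0.0) -> FrontStatRow:
    """Summarise one column of demes given its per-deme allele counts.

    PX is the unweighted mean of within-deme pairwise differences over the
    column's demes; PXY and Pc are unweighted means over all C(N, 2)
    unordered deme pairs.  Segmentation counts/widths and ``fbar`` are
    attached from the column's frequency profile.
    """
    nA = np.asarray(nA, dtype=np.int64)
    na = np.asarray(na, dtype=np.int64)
    size = nA + na
    if np.any(size < 2):
        raise ValueError("every deme needs at least 2 individuals")
    n = size.astype(float)
    p = nA / n
    px_within = 2.0 * nA * na / (n * (n - 1.0))
    # All unordered deme pairs via broadcasting (N is small).
    pxy = p[:, None] * (1.0 - p[None, :]) + p[None, :] * (1.0 - p[:, None])
    pc = pxy - (px_within[:, None] + px_within[None, :]) / 2.0
    iu = np.triu_indices(p.size, k=1)
    seg = segment_column(p, atol=atol)
    return FrontStatRow(
        n_domains=seg.n_domains,
        n_clines=seg.n_clines,
        mean_domain_width=seg.mean_domain_width,
        mean_cline_width=seg.mean_cline_width,
        PX=float(px_within.mean()),
        PXY=float(pxy[iu].mean()),
        Pc=float(pc[iu].mean()),
        fbar=fbar(p),
    )


STAT_COLUMNS = ["n_domains", "n_clines", "mean_domain_width", "mean_cline_width",
                "PX", "PXY", "Pc", "fbar"]


def records_to_frame(records: Iterable[FrozenRecord], replicate: int = 0) -> pd.DataFrame:
    """Long-format table of frozen records: one row per (column, deme row).

    Columns: replicate, column_index, generation_recorded, row_index,
    frequency.  Row and column indices are 1-based.
    """
    rows = []
    for rec in records:
        freqs = rec.frequencies
        for i, f in enumerate(freqs, start=1):
            rows.append((replicate, rec.column_index, rec.generation_recorded, i, f))
    return pd.DataFrame(
        rows, columns=["replicate", "column_index", "generation_recorded",
                       "row_index", "frequency"],
    )


def stats_frame(records: Iterable[FrozenRecord], replicate: int = 0) -> pd.DataFrame:
    """Per-column statistic table: one FrontStatRow per frozen record."""
    rows = []
    for rec in records:
        st = front_stats(rec.nA, rec.K - rec.nA)
        rows.append({
            "replicate": replicate,
            "column_index": rec.column_index,
            "generation_recorded": rec.generation_recorded,
            **{k: getattr(st, k) for k in STAT_COLUMNS},
        })
    return pd.DataFrame(rows, columns=["replicate", "column_index",
                                       "generation_recorded", *STAT_COLUMNS])


def stats_from_record_table(table: pd.DataFrame, K: int) -> pd.DataFrame:
    """Recompute per-column statistics from a stored long-format record table."""
    out = []
    for (rep, col, gen), grp in table.groupby(
            ["replicate", "column_index", "generation_recorded"], sort=True):
        grp = grp.sort_values("row_index")
        nA = np.rint(grp["frequency"].to_numpy() * K).astype(np.int64)
        st = front_stats(nA, K - nA)
        out.append({"replicate": rep, "column_index": col,
                    "generation_recorded": gen,
                    **{k: getattr(st, k) for k in STAT_COLUMNS}})
    return pd.DataFrame(out, columns=["replicate", "column_index",
                                      "generation_recorded", *STAT_COLUMNS])


# --------------------------------------------------------------------------
# Experiment runner: replicate sweeps over parameter grids
# --------------------------------------------------------------------------


@dataclass
class SweepSpec:
    """A replicate sweep: a base parameterisation, a grid of varied fields,
    a replicate count and a base seed.  Replicate i of every combination uses
    seed ``base_seed + i``."""

    base: SimParams
    varied: Mapping[str, Sequence] = field(default_factory=dict)
    n_replicates: int = 10
    base_seed: int = 0
    output_dir: Path | None = None

    def combinations(self) -> list[dict]:
        """Cartesian product of the varied fields, with BLRE-only fields
        normalised away (and duplicates dropped) for non-BLRE combos."""
        if not self.varied:
            return [{}]
        names = sorted(self.varied)
        combos = []
        seen = set()
        for values in itertools.product(*(self.varied[n] for n in names)):
            combo = dict(zip(names, values))
            scenario = _canonical_scenario(
                combo.get("scenario", self.base.scenario))
            if scenario != "BLRE" and "boundary_duration" in combo:
                combo["boundary_duration"] = None
            key = tuple(sorted(combo.items()))
            if key not in seen:
                seen.add(key)
                combos.append(combo)
        return combos


@dataclass
class AveragedTrajectory:
    """Replicate-averaged per-column statistics for each parameter combination.

    ``tables`` maps a combination label to a DataFrame indexed by
    column_index with mean/std/count of each statistic; ``expansion_times``
    maps the label to the mean expansion time over replicates (nan if no
    replicate completed)."""

    tables: dict[str, pd.DataFrame]
    expansion_times: dict[str, float]
    specs: dict[str, SimParams]


def combo_label(combo: Mapping[str, object]) -> str:
    if not combo:
        return "base"
    return "_".join(f"{k}={v}" for k, v in sorted(combo.items()))


def _average_stats(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean/std/contributing-count per column over replicates.

    None-valued widths (columns with no cline or no domain in a replicate)
    are ignored; the count columns record how many replicates contributed.
    """
    grouped = replicates.groupby("column_index")
    pieces = {"generation_recorded_mean": grouped["generation_recorded"].mean()}
    for stat in STAT_COLUMNS:
        pieces[f"{stat}_mean"] = grouped[stat].mean()
        pieces[f"{stat}_std"] = grouped[stat].std()
        pieces[f"{stat}_n"] = grouped[stat].count()
    return pd.DataFrame(pieces)


def run_sweep(spec: SweepSpec) -> AveragedTrajectory:
    """Run every parameter combination for ``n_replicates`` replicates,
    compute front statistics on all frozen records, and average per column.

    Deterministic given ``base_seed``: replicate i always uses seed
    ``base_seed + i``.  When ``spec.output_dir`` is set, each combination gets
    a directory with ``replicates.tsv``, ``averaged.tsv`` and a
    ``manifest.json`` of the exact parameters and seeds.
    """
    if spec.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    valid_fields = set(SimParams.__dataclass_fields__)
    for name in spec.varied:
        if name not in valid_fields:
            raise ValueError(f"unknown SimParams field in sweep: {name!r}")

    tables: dict[str, pd.DataFrame] = {}
    expansion_times: dict[str, float] = {}
    specs: dict[str, SimParams] = {}
    for combo in spec.combinations():
        label = combo_label(combo)
        params0 = replace(spec.base, **combo)
        rep_frames = []
        times = []
        for i in range(spec.n_replicates):
            seed = spec.base_seed + i
            params = replace(params0, seed=seed)
            try:
                result = run(params)
            except Exception as exc:  # abort with the failing seed named
                raise RuntimeError(
                    f"replicate {i} (seed {seed}) of combination {label!r} failed"
                ) from exc
            sf = stats_frame(result.records, replicate=i)
            rep_frames.append(sf)
            times.append(result.expansion_time)
            logger.info("combo %s replicate %d: %d records, expansion_time=%s",
                        label, i, len(result.records), result.expansion_time)
        replicates = pd.concat(rep_frames, ignore_index=True)
        averaged = _average_stats(replicates)
        finished = [t for t in times if t is not None]
        mean_time = float(np.mean(finished)) if finished else float("nan")
        tables[label] = averaged
        expansion_times[label] = mean_time
        specs[label] = params0

        if spec.output_dir is not None:
            out = Path(spec.output_dir) / label
            out.mkdir(parents=True, exist_ok=True)
            replicates.to_csv(out / "replicates.tsv", sep="\t", index=False,
                              float_format="%.10g")
            averaged.to_csv(out / "averaged.tsv", sep="\t",
                            float_format="%.10g")
            manifest = {
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(params0).items()},
                "n_replicates": spec.n_replicates,
                "seeds": [spec.base_seed + i for i in range(spec.n_replicates)],
                "expansion_times": times,
                "mean_expansion_time": mean_time,
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return AveragedTrajectory(tables=tables, expansion_times=expansion_times,
                              specs=specs)


PRESET_NAMES = ("fig2_boundary_speeds", "fig3_migration", "fig4_reproduction",
                "fig5_init_freq", "stationary_baseline", "pilot_expansion_time")


def preset(name: str, *, variant: str = "methods", n_replicates: int = 10,
           base_seed: int = 0, output_dir: Path | None = None) -> SweepSpec:
    """Parameter grid for one of the reference experiments, at a desk-scale
    default of 10 replicates (the full study used 100; pass
    ``n_replicates=100`` for that).

    ``variant`` selects between the two published parameter lists where they
    disagree: ``"methods"`` (boundary durations starting at 600, r up to 5,
    m down to 0.01) or ``"caption"`` (durations starting at 800, r up to 4,
    m down to 0.001).
    """
    if variant not in ("methods", "caption"):
        raise ValueError("variant must be 'methods' or 'caption'")
    base = SimParams(scenario="BLRE", boundary_duration=6000)
    common = dict(n_replicates=n_replicates, base_seed=base_seed,
                  output_dir=output_dir)
    if name == "fig2_boundary_speeds":
        durations = BLRE_DURATIONS_METHODS if variant == "methods" else BLRE_DURATIONS_CAPTION
        return SweepSpec(base=base,
                         varied={"scenario": ["PhLRE", "BLRE"],
                                 "boundary_duration": list(durations)},
                         **common)
    if name == "fig3_migration":
        ms = [0.01, 0.1, 0.2, 0.4] if variant == "methods" else [0.001, 0.01, 0.1, 0.2, 0.4]
        return SweepSpec(base=base,
                         varied={"scenario": ["PhLRE", "BLRE"], "m": ms},
                         **common)
    if name == "fig4_reproduction":
        rs = [1.1, 2, 3, 5] if variant == "methods" else [1.1, 2, 3, 4]
        return SweepSpec(base=base,
                         varied={"scenario": ["PhLRE", "BLRE"], "r": rs},
                         **common)
    if name == "fig5_init_freq":
        return SweepSpec(base=base,
                         varied={"scenario": ["PhLRE", "BLRE"],
                                 "p0": [0.01, 0.1, 0.2, 0.5]},
                         **common)
    if name == "stationary_baseline":
        return SweepSpec(base=SimParams(scenario="stationary"), **common)
    if name == "pilot_expansion_time":
        return SweepSpec(base=SimParams(scenario="PhLRE"), **common)
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


def mean_expansion_time(params: SimParams, n_replicates: int,
                        base_seed: int = 0) -> tuple[float, float, list[int]]:
    """Mean and standard deviation of the expansion time over replicates.

    Replicate i uses seed ``base_seed + i``.  Replicates that never complete
    within ``max_generations`` raise, since the mean would be undefined.
    """
    times = []
    for i in range(n_replicates):
        result = run(replace(params, seed=base_seed + i))
        if result.expansion_time is None:
            raise RuntimeError(
                f"replicate {i} (seed {base_seed + i}) did not complete "
                f"within {params.max_generations} generations")
        times.append(result.expansion_time)
    arr = np.asarray(times, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), times


# --------------------------------------------------------------------------
# Config files & plotting helper
# --------------------------------------------------------------------------


def load_params(path: str | Path) -> SimParams:
    """Load a SimParams from a YAML or JSON mapping (field-for-field)."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of SimParams fields")
    if "snapshot_generations" in data and data["snapshot_generations"] is not None:
        data["snapshot_generations"] = tuple(data["snapshot_generations"])
    return SimParams(**data)


def plot_record_heatmap(records: Sequence[FrozenRecord], n_cols: int, ax=None):
    """Render frozen records as a rows × columns frequency heatmap (green =
    fixed a, red = fixed A, black = never recorded).  Requires matplotlib."""
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("no records to plot")
    n_rows = records[0].nA.size
    grid = np.full((n_rows, n_cols), np.nan)
    for rec in records:
        grid[:, rec.column_index - 1] = rec.frequencies
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    cmap = mcolors.LinearSegmentedColormap.from_list(
        "allele", ["green", "yellow", "red"])
    cmap.set_bad("black")
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=0, vmax=1,
              interpolation="nearest")
    ax.set_xlabel("column (expansion axis)")
    ax.set_ylabel("row")
    return ax
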