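"""Admixture scenarios, parameter priors, and per-generation schedules.

The admixed population H is founded at generation 0 from two source
populations (labelled ``Afr`` and ``Eur``) and evolves for 20 further
generations.  Four competing historical scenarios combine, per source,
either two post-founding admixture pulses (``2Pulses``) or a period of
monotonically non-increasing recurring admixture (``Recurring``).  A
parameter draw fully determines a deterministic per-generation schedule
of source contributions (s_Afr,g, s_Eur,g) and the contribution h_g of
the admixed population to itself, with s_Afr,g + s_Eur,g + h_g = 1 for
every g >= 1 and s_Afr,0 + s_Eur,0 = 1 at founding.

The reproductive population size N_g follows a rectangular-hyperbola
interpolation between N_0 and N_20 whose steepness is set by u_N in
[0, 0.5]: u_N = 0.5 is the linear limit, u_N -> 0 keeps N_g ~ N_0 until
a sharp final increase.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "SCENARIOS",
    "GENERATIONS",
    "AFRICAN",
    "EUROPEAN",
    "DemographyParams",
    "PulseProcess",
    "RecurringProcess",
    "ParameterVector",
    "ContributionSchedule",
    "PriorSpec",
    "InvalidParameterError",
    "ConstraintViolationError",
    "population_size_at",
    "recurring_intensity_at",
    "build_schedule",
    "draw_parameters",
    "PARAMETER_COLUMNS",
    "parameter_record",
    "vector_from_record",
]

#: generation indices run 0..20 inclusive (founding at 0)
GENERATIONS = 21

AFRICAN = "African"
EUROPEAN = "European"

SCENARIOS = (
    "Afr2Pulses-Eur2Pulses",
    "Afr2Pulses-EurRecurring",
    "AfrRecurring-Eur2Pulses",
    "AfrRecurring-EurRecurring",
)


class InvalidParameterError(ValueError):
    """A parameter lies outside its prior bounds or violates a condition."""


class ConstraintViolationError(ValueError):
    """A schedule generation would need s_Afr,g + s_Eur,g > 1."""


@dataclass(frozen=True)
class DemographyParams:
    """Reproductive population-size trajectory parameters.

    N0, N20 are diploid individual counts at generations 0 and 20;
    uN in [0, 0.5] sets the steepness of the hyperbolic increase.
    """

    N0: int
    N20: int
    uN: float

    def __post_init__(self):
        if not (10 <= self.N0 <= 1000):
            raise InvalidParameterError(f"N0={self.N0} outside [10, 1000]")
        if not (100 <= self.N20 <= 100_000):
            raise InvalidParameterError(f"N20={self.N20} outside [100, 100000]")
        if self.N0 > self.N20:
            raise InvalidParameterError(f"N0={self.N0} > N20={self.N20}")
        if not (0.0 <= self.uN <= 0.5):
            raise InvalidParameterError(f"uN={self.uN} outside [0, 0.5]")


@dataclass(frozen=True)
class PulseProcess:
    """Two one-generation admixture pulses from one source.

    By convention (prior table ordering) t_p1 > t_p2: the first-labelled
    pulse is the more recent one.  Intensities are proportions in [0, 1].
    """

    source: str
    t_p1: int
    t_p2: int
    s_p1: float
    s_p2: float

    def __post_init__(self):
        for t in (self.t_p1, self.t_p2):
            if not (1 <= t <= 20):
                raise InvalidParameterError(f"pulse time {t} outside [1, 20]")
        if self.t_p1 == self.t_p2:
            raise InvalidParameterError("pulse times must be distinct")
        if self.t_p1 < self.t_p2:
            raise InvalidParameterError("label ordering requires t_p1 > t_p2")
        for s in (self.s_p1, self.s_p2):
            if not (0.0 <= s <= 1.0):
                raise InvalidParameterError(f"pulse intensity {s} outside [0, 1]")


@dataclass(frozen=True)
class RecurringProcess:
    """A period [t_t1, t_t2] of monotonically non-increasing admixture.

    Intensity decays from s_t1 at the period start to s_t2 at its end
    along a decreasing rectangular hyperbola of steepness u: u = 0.5 is
    the linear decay limit, u -> 0 a sharp initial pulse followed by
    constant intensity s_t2.
    """

    source: str
    t_t1: int
    t_t2: int
    s_t1: float
    s_t2: float
    u: float

    def __post_init__(self):
        for t in (self.t_t1, self.t_t2):
            if not (1 <= t <= 20):
                raise InvalidParameterError(f"period time {t} outside [1, 20]")
        if self.t_t2 < self.t_t1 + 1:
            raise InvalidParameterError("period requires t_t2 >= t_t1 + 1")
        for s in (self.s_t1, self.s_t2):
            if not (0.0 <= s <= 1.0):
                raise InvalidParameterError(f"intensity {s} outside [0, 1]")
        if self.s_t1 < self.s_t2:
            raise InvalidParameterError("requires s_t1 >= s_t2")
        if not (0.0 <= self.u <= 0.5):
            raise InvalidParameterError(f"u={self.u} outside [0, 0.5]")


Process = Union[PulseProcess, RecurringProcess]


def _process_kind(p: Process) -> str:
    return "2Pulses" if isinstance(p, PulseProcess) else "Recurring"


@dataclass(frozen=True)
class ParameterVector:
    """One complete draw of scenario parameters."""

    scenario: str
    s_Afr_0: float
    african_process: Process
    european_process: Process
    demography: DemographyParams

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InvalidParameterError(f"unknown scenario {self.scenario!r}")
        if not (0.0 <= self.s_Afr_0 <= 1.0):
            raise InvalidParameterError("s_Afr_0 outside [0, 1]")
        want = f"Afr{_process_kind(self.african_process)}-Eur{_process_kind(self.european_process)}"
        if want != self.scenario:
            raise InvalidParameterError(
                f"process kinds {want} inconsistent with scenario {self.scenario}"
            )
        if self.african_process.source != AFRICAN:
            raise InvalidParameterError("african_process must be labelled African")
        if self.european_process.source != EUROPEAN:
            raise InvalidParameterError("european_process must be labelled European")

    @property
    def s_Eur_0(self) -> float:
        return 1.0 - self.s_Afr_0


@dataclass(frozen=True)
class ContributionSchedule:
    """Per-generation (s_Afr,g, s_Eur,g, h_g) rows for g = 0..20."""

    s_afr: np.ndarray
    s_eur: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        for a in (self.s_afr, self.s_eur, self.h):
            if a.shape != (GENERATIONS,):
                raise ValueError("schedule arrays must have length 21")
        total = self.s_afr + self.s_eur + self.h
        if abs(self.s_afr[0] + self.s_eur[0] - 1.0) > 1e-12 or self.h[0] != 0.0:
            raise ConstraintViolationError("founding row must have s_Afr,0 + s_Eur,0 = 1, h_0 = 0")
        if np.any(np.abs(total[1:] - 1.0) > 1e-12):
            raise ConstraintViolationError("rows g >= 1 must sum to 1")
        for a in (self.s_afr, self.s_eur, self.h):
            if np.any((a < 0) | (a > 1)):
                raise ConstraintViolationError("schedule entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior ranges for every scenario parameter.

    Defaults are the study priors: pulse/period times discrete uniform on
    [1, 20]; all intensities uniform on [0, 1]; N0 uniform on [10, 1000];
    N20 uniform on [100, 100000] with N0 <= N20; steepness parameters
    uniform on [0, 0.5].
    """

    t_range: tuple[int, int] = (1, 20)
    s_range: tuple[float, float] = (0.0, 1.0)
    s_afr0_range: tuple[float, float] = (0.0, 1.0)
    n0_range: tuple[int, int] = (10, 1000)
    n20_range: tuple[int, int] = (100, 100_000)
    u_range: tuple[float, float] = (0.0, 0.5)
    max_attempts: int = 10_000

    def bounds_for(self, name: str) -> tuple[float, float]:
        """Prior bounds for a named parameter column (for ABC transforms)."""
        if name == "s_Afr_0":
            return self.s_afr0_range
        if name.startswith("t_"):
            return (float(self.t_range[0]), float(self.t_range[1]))
        if name.startswith("s_"):
            return self.s_range
        if name == "N0":
            return (float(self.n0_range[0]), float(self.n0_range[1]))
        if name == "N20":
            return (float(self.n20_range[0]), float(self.n20_range[1]))
        if name.startswith("u"):
            return self.u_range
        raise KeyError(name)


# ---------------------------------------------------------------------------
# operations


def _check_demography(d: DemographyParams) -> None:
    # dataclass validates on construction; re-validate in case of mutation
    DemographyParams(d.N0, d.N20, d.uN)


def population_size_at(demography: DemographyParams, g: int) -> int:
    """Reproductive size N_g at generation g (diploid individuals).

    Discrete points of an increasing rectangular hyperbola between N_0
    and N_20:  N(g) = N0 + (N20 - N0) * g*k / (20*k + 20 - g) with
    k = uN / (0.5 - uN); uN = 0.5 is the exact linear-interpolation
    limit.  Values are rounded half-up to whole individuals.
    """
    _check_demography(demography)
    if not (isinstance(g, (int, np.integer)) and 0 <= g <= 20):
        raise InvalidParameterError(f"generation {g} outside [0, 20]")
    n0, n20, u = demography.N0, demography.N20, demography.uN
    if g == 0:
        return int(n0)
    if g == 20:
        return int(n20)
    if u >= 0.5:
        frac = g / 20.0
    elif u <= 0.0:
        frac = 0.0
    else:
        k = u / (0.5 - u)
        frac = (g * k) / (20.0 * k + 20.0 - g)
    return int(math.floor(n0 + (n20 - n0) * frac + 0.5))


def recurring_intensity_at(process: RecurringProcess, g: int) -> float:
    """Admixture intensity during a recurring period at generation g.

    Decreasing rectangular hyperbola from s_t1 (at t_t1) to s_t2 (at
    t_t2); u = 0.5 gives linear decay, u -> 0 a sharp initial drop to
    s_t2 one generation after the period starts.
    """
    if not (process.t_t1 <= g <= process.t_t2):
        raise InvalidParameterError(
            f"generation {g} outside period [{process.t_t1}, {process.t_t2}]"
        )
    s1, s2, u = process.s_t1, process.s_t2, process.u
    D = process.t_t2 - process.t_t1
    d = g - process.t_t1
    if d == 0:
        return s1
    if d == D:
        return s2
    if u >= 0.5:
        frac = d / D
    elif u <= 0.0:
        frac = 1.0
    else:
        k = u / (0.5 - u)
        frac = 1.0 - (D - d) * k / (D * k + d)
    return s1 - (s1 - s2) * frac


def build_schedule(params: ParameterVector) -> ContributionSchedule:
    """Expand a parameter vector into the 21-row contribution schedule.

    Generations hit by a pulse receive that pulse's intensity; those
    inside a recurring period receive the hyperbolic decay value; all
    others receive zero source contribution (h_g = 1).  Raises
    ConstraintViolationError if any generation would need
    s_Afr,g + s_Eur,g > 1 (callers reject the draw).
    """
    s_afr = np.zeros(GENERATIONS)
    s_eur = np.zeros(GENERATIONS)
    s_afr[0] = params.s_Afr_0
    s_eur[0] = params.s_Eur_0
    for proc, out in ((params.african_process, s_afr), (params.european_process, s_eur)):
        if isinstance(proc, PulseProcess):
            out[proc.t_p1] = proc.s_p1
            out[proc.t_p2] = proc.s_p2
        else:
            for g in range(proc.t_t1, proc.t_t2 + 1):
                out[g] = recurring_intensity_at(proc, g)
    if np.any(s_afr[1:] + s_eur[1:] > 1.0 + 1e-12):
        raise ConstraintViolationError(
            "s_Afr,g + s_Eur,g > 1 at some generation; reject and redraw"
        )
    h = 1.0 - s_afr - s_eur
    h[0] = 0.0
    return ContributionSchedule(s_afr=s_afr, s_eur=s_eur, h=np.clip(h, 0.0, 1.0))


def _draw_process(prior: PriorSpec, source: str, kind: str, rng: np.random.Generator) -> Process:
    lo, hi = prior.t_range
    if kind == "2Pulses":
        t1, t2 = rng.choice(np.arange(lo, hi + 1), size=2, replace=False)
        t1, t2 = int(max(t1, t2)), int(min(t1, t2))
        s1, s2 = rng.uniform(*prior.s_range, size=2)
        return PulseProcess(source=source, t_p1=t1, t_p2=t2, s_p1=float(s1), s_p2=float(s2))
    t1, t2 = rng.choice(np.arange(lo, hi + 1), size=2, replace=False)
    t1, t2 = int(min(t1, t2)), int(max(t1, t2))
    s1, s2 = np.sort(rng.uniform(*prior.s_range, size=2))[::-1]
    u = rng.uniform(*prior.u_range)
    return RecurringProcess(
        source=source, t_t1=t1, t_t2=t2, s_t1=float(s1), s_t2=float(s2), u=float(u)
    )


def draw_parameters(
    prior: PriorSpec, scenario: str, rng: np.random.Generator
) -> ParameterVector:
    """Draw one parameter vector from the priors under a scenario.

    Uniform draws subject to the prior table's conditions (time and
    intensity orderings, N0 <= N20); vectors whose schedule would
    violate s_Afr,g + s_Eur,g <= 1 at any generation are rejected and
    redrawn, preserving uniformity on the feasible region.
    """
    if scenario not in SCENARIOS:
        raise InvalidParameterError(f"unknown scenario {scenario!r}")
    afr_kind = "2Pulses" if "Afr2Pulses" in scenario else "Recurring"
    eur_kind = "2Pulses" if "Eur2Pulses" in scenario else "Recurring"
    for _ in range(prior.max_attempts):
        # N0 <= N20 by rejection keeps both marginals conditionally uniform
        n0 = int(rng.integers(prior.n0_range[0], prior.n0_range[1] + 1))
        n20 = int(rng.integers(prior.n20_range[0], prior.n20_range[1] + 1))
        if n0 > n20:
            continue
        demog = DemographyParams(N0=n0, N20=n20, uN=float(rng.uniform(*prior.u_range)))
        params = ParameterVector(
            scenario=scenario,
            s_Afr_0=float(rng.uniform(*prior.s_afr0_range)),
            african_process=_draw_process(prior, AFRICAN, afr_kind, rng),
            european_process=_draw_process(prior, EUROPEAN, eur_kind, rng),
            demography=demog,
        )
        try:
            build_schedule(params)
        except ConstraintViolationError:
            continue
        return params
    raise RuntimeError(f"no feasible draw after {prior.max_attempts} attempts")


# ---------------------------------------------------------------------------
# serialization

#: fixed column order for parameter records; columns absent from a
#: scenario are NA
PARAMETER_COLUMNS = (
    "scenario",
    "s_Afr_0",
    "t_Afr_p1", "t_Afr_p2", "s_Afr_p1", "s_Afr_p2",
    "t_Afr_t1", "t_Afr_t2", "s_Afr_t1", "s_Afr_t2", "u_Afr",
    "t_Eur_p1", "t_Eur_p2", "s_Eur_p1", "s_Eur_p2",
    "t_Eur_t1", "t_Eur_t2", "s_Eur_t1", "s_Eur_t2", "u_Eur",
    "N0", "N20", "uN",
)


def vector_from_record(rec) -> ParameterVector:
    """Rebuild a ParameterVector from a flat record (inverse of
    :func:`parameter_record`); `rec` is any mapping or namespace with the
    PARAMETER_COLUMNS fields."""
    get = rec.get if hasattr(rec, "get") else lambda k: getattr(rec, k)
    scen = get("scenario")
    if "Afr2Pulses" in scen:
        afr = PulseProcess(AFRICAN, int(get("t_Afr_p1")), int(get("t_Afr_p2")),
                           float(get("s_Afr_p1")), float(get("s_Afr_p2")))
    else:
        afr = RecurringProcess(AFRICAN, int(get("t_Afr_t1")), int(get("t_Afr_t2")),
                               float(get("s_Afr_t1")), float(get("s_Afr_t2")),
                               float(get("u_Afr")))
    if "Eur2Pulses" in scen:
        eur = PulseProcess(EUROPEAN, int(get("t_Eur_p1")), int(get("t_Eur_p2")),
                           float(get("s_Eur_p1")), float(get("s_Eur_p2")))
    else:
        eur = RecurringProcess(EUROPEAN, int(get("t_Eur_t1")), int(get("t_Eur_t2")),
                               float(get("s_Eur_t1")), float(get("s_Eur_t2")),
                               float(get("u_Eur")))
    return ParameterVector(
        scenario=scen,
        s_Afr_0=float(get("s_Afr_0")),
        african_process=afr,
        european_process=eur,
        demography=DemographyParams(int(get("N0")), int(get("N20")),
                                    float(get("uN"))),
    )


def parameter_record(params: ParameterVector) -> dict:
    """Flatten a ParameterVector into the fixed TSV column dict."""
    rec = {c: float("nan") for c in PARAMETER_COLUMNS}
    rec["scenario"] = params.scenario
    rec["s_Afr_0"] = params.s_Afr_0
    for tag, proc in (("Afr", params.african_process), ("Eur", params.european_process)):
        if isinstance(proc, PulseProcess):
            rec[f"t_{tag}_p1"] = proc.t_p1
            rec[f"t_{tag}_p2"] = proc.t_p2
            rec[f"s_{tag}_p1"] = proc.s_p1
            rec[f"s_{tag}_p2"] = proc.s_p2
        else:
            rec[f"t_{tag}_t1"] = proc.t_t1
            rec[f"t_{tag}_t2"] = proc.t_t2
            rec[f"s_{tag}_t1"] = proc.s_t1
            rec[f"s_{tag}_t2"] = proc.s_t2
            rec[f"u_{tag}"] = proc.u
    rec["N0"] = params.demography.N0
    rec["N20"] = params.demography.N20
    rec["uN"] = params.demography.uN
    return rec
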