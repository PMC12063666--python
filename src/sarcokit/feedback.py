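"""Titin-instructed biomechanical feedback model of sarcomere filament length.

The model tracks three characteristic lengths of a half-sarcomere over
alternating contraction/relaxation phases:

* ``L_I`` — the I-band titin spring. It toggles between a long relaxed
  equilibrium ``L_I_max`` and a compressed length
  ``L_I_min = L_I_max - T_motor / K_titin`` set by the balance of maximal
  motor compression force against titin's linear elasticity.
* ``L_actin`` — the thin filament. It polymerises during relaxation at
  ``v_actin_r`` up to a maximal length ``L_I_max + alpha`` (once the
  actomyosin overlap recruits a critical number of motors, strong
  contractions block further subunit addition), and during contraction at
  ``v_actin_c`` capped by the wall condition with the compressed I-band.
* ``L_A_band`` — the thick filament. It grows only during relaxation, at
  ``v_A_r``, and halts once the contracted sarcomere would be fully
  overlapped (``L_A >= L_actin - L_I_min``).

The wall condition ``L_actin <= L_I + L_A_band`` (actin cannot cross the
sarcomere midline) holds at every instant. All dynamics are piecewise
linear, so the trajectory is integrated *exactly* by solving for event
times (phase switches, caps, constraint activations) in closed form; there
is no time-stepping error.

For any positive growth rates and a periodic contraction schedule the
system converges to the fixed point

    L_actin(inf) = L_I_max + alpha
    L_A_band(inf) = L_I_max + alpha - L_I_min

i.e. both filament lengths scale affinely (unit slope) with the relaxed
I-band length — short stiff titin instructs short filaments (flight-type
sarcomeres), long compliant titin instructs long filaments (larval
crawling-type sarcomeres).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SarcomereState",
    "Trajectory",
    "FixedPoint",
    "PhaseDiagramGrid",
    "derive_L_I_min",
    "simulate",
    "fixed_point",
    "phase_diagram",
    "time_to_converge",
    "classify_sarcomere",
    "scenario",
    "SCENARIO_NAMES",
]

_EPS = 1e-12

Schedule = Literal["periodic", "none"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the feedback model.

    Lengths are in μm and times in arbitrary units (hours recommended);
    the dynamics are scale free so any consistent unit system works.

    ``alpha`` is the extra actin length beyond the relaxed I-band at which
    strong contractions start (alpha = N_c * l for a critical motor count
    N_c and per-motor length scale l); it may be given directly or through
    ``N_c`` and ``l``.
    """

    L_I_max: float
    T_motor: float
    K_titin: float
    alpha: float | None = None
    N_c: float | None = None
    l: float | None = None
    T_c: float = 1.0
    T_r: float = 1.0
    v_actin_r: float = 0.02
    v_A_r: float = 0.02
    v_actin_c: float = 0.0
    L_actin_0: float = 0.0
    L_A_0: float = 0.0
    total_time: float = 100.0
    contraction_schedule: Schedule = "periodic"
    stop_contractions_after: float | None = None
    sarcomere_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha is None:
            if self.N_c is None or self.l is None:
                raise ValueError("provide alpha, or both N_c and l")
            object.__setattr__(self, "alpha", self.N_c * self.l)
        if self.K_titin <= 0:
            raise ValueError("K_titin must be positive")
        if self.L_I_min <= 0:
            raise ValueError(
                "titin over-compressed: L_I_max - T_motor/K_titin must be > 0"
            )
        for name in ("v_actin_r", "v_A_r", "v_actin_c", "T_c", "T_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        # wall condition on the initial state (relaxed I-band)
        if self.L_actin_0 > self.L_I_max + self.L_A_0 + _EPS:
            raise ValueError(
                "initial condition violates the wall condition "
                "L_actin_0 <= L_I_max + L_A_0"
            )
        if self.contraction_schedule not in ("periodic", "none"):
            raise ValueError(f"unknown schedule {self.contraction_schedule!r}")

    @property
    def L_I_min(self) -> float:
        return self.L_I_max - self.T_motor / self.K_titin


@dataclass(frozen=True)
class SarcomereState:
    t: float
    L_actin: float
    L_A_band: float
    L_I_band: float
    phase: Literal["relaxation", "contraction"]

    @property
    def sarcomere_length(self) -> float:
        return 2.0 * (self.L_I_band + self.L_A_band)


@dataclass
class Trajectory:
    """Ordered states recorded at phase boundaries and cap-hitting events."""

    params: ModelParams
    states: list[SarcomereState] = field(default_factory=list)

    @property
    def final(self) -> SarcomereState:
        return self.states[-1]

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {
            "t": np.array([s.t for s in self.states]),
            "L_actin": np.array([s.L_actin for s in self.states]),
            "L_A_band": np.array([s.L_A_band for s in self.states]),
            "L_I_band": np.array([s.L_I_band for s in self.states]),
        }


@dataclass(frozen=True)
class FixedPoint:
    L_actin_inf: float
    L_A_inf: float
    L_I_relaxed: float
    sarcomere_length_inf: float


def derive_L_I_min(params: ModelParams) -> float:
    """Compressed I-band length L_I_min = L_I_max - T_motor / K_titin."""
    return params.L_I_min


def fixed_point(params: ModelParams) -> FixedPoint:
    """Closed-form final lengths under a periodic schedule, positive rates."""
    la = params.L_I_max + params.alpha
    lab = la - params.L_I_min
    return FixedPoint(
        L_actin_inf=la,
        L_A_inf=lab,
        L_I_relaxed=params.L_I_max,
        sarcomere_length_inf=params.sarcomere_factor * (params.L_I_max + lab),
    )


def _relaxation_rates(
    p: ModelParams, L_actin: float, L_A: float
) -> tuple[float, float]:
    """Effective growth rates inside a relaxation phase.

    Constraints (all caps, no shrink dynamics):
      C1  L_actin <= L_I_max + alpha          -> actin rate 0 when active
      C2  L_actin <= L_I_max + L_A (wall)     -> actin tracks A-band growth
      C3  L_A     <= L_actin - L_I_min        -> A-band tracks actin growth
    Rates are obtained by projecting (v_actin_r, v_A_r) onto the active
    constraint set; the coupled caps make the projection a short fixed
    point iteration (monotone, converges in <= 2 passes).
    """
    r_a = p.v_actin_r
    r_A = p.v_A_r
    for _ in range(3):
        prev = (r_a, r_A)
        halt_line = L_actin - p.L_I_min
        if L_A > halt_line + _EPS:  # strictly above: A-band halted
            r_A = 0.0
        elif L_A >= halt_line - _EPS:  # on the line: track actin growth
            r_A = min(p.v_A_r, r_a)
        if L_actin >= p.L_I_max + L_A - _EPS:  # C2 active
            r_a = min(p.v_actin_r, r_A)
        if L_actin >= p.L_I_max + p.alpha - _EPS:  # C1 active
            r_a = 0.0
        if (r_a, r_A) == prev:
            break
    return r_a, r_A


def _next_relaxation_event(
    p: ModelParams, L_actin: float, L_A: float, r_a: float, r_A: float
) -> float:
    """Time until the first inactive constraint becomes active (inf if none)."""
    dts = []
    if r_a > _EPS:
        gap = p.L_I_max + p.alpha - L_actin
        if gap > _EPS:
            dts.append(gap / r_a)
    if r_a - r_A > _EPS:
        gap = p.L_I_max + L_A - L_actin
        if gap > _EPS:
            dts.append(gap / (r_a - r_A))
    if r_A - r_a > _EPS:
        gap = L_actin - p.L_I_min - L_A
        if gap > _EPS:
            dts.append(gap / (r_A - r_a))
    if r_a - r_A > _EPS:
        # halted A-band above the line: actin catches up, tracking resumes
        gap = L_A - (L_actin - p.L_I_min)
        if gap > _EPS:
            dts.append(gap / (r_a - r_A))
    return min(dts) if dts else math.inf


def simulate(params: ModelParams) -> Trajectory:
    """Integrate the model exactly, event by event.

    The trajectory records a state at t=0, at every constraint-activation
    event, and at every phase boundary; lengths are piecewise linear in
    between. The state stored at a phase-boundary time is the state at the
    start of the new phase (after the I-band toggles and, on contraction
    onset, after the wall clamp on actin).
    """
    p = params
    traj = Trajectory(params=p)
    L_actin = p.L_actin_0
    L_A = p.L_A_0
    cycle = p.T_r + p.T_c

    def phases():
        """Yield (is_contraction, t_start, t_end) covering [0, total_time].

        A cycle starts with a relaxation phase; boundaries are computed
        from an integer cycle counter so float drift cannot accumulate.
        Contractions cease at the first phase boundary at or after
        ``stop_contractions_after``.
        """
        if p.contraction_schedule == "none":
            yield False, 0.0, p.total_time
            return
        k = 0
        while True:
            for is_c, start, end in (
                (False, k * cycle, k * cycle + p.T_r),
                (True, k * cycle + p.T_r, (k + 1) * cycle),
            ):
                if start >= p.total_time - _EPS:
                    return
                if is_c and (
                    p.stop_contractions_after is not None
                    and start >= p.stop_contractions_after - _EPS
                ):
                    yield False, start, p.total_time
                    return
                yield is_c, start, min(end, p.total_time)
            k += 1

    first = True
    for in_contraction, t, t_phase in phases():
        if in_contraction:
            L_actin = min(L_actin, p.L_I_min + L_A)
        L_I = p.L_I_min if in_contraction else p.L_I_max
        label = "contraction" if in_contraction else "relaxation"
        if first:
            traj.states.append(SarcomereState(t, L_actin, L_A, L_I, label))
            first = False
        else:
            # phase-boundary record: state at the start of the new phase
            traj.states.append(SarcomereState(t, L_actin, L_A, L_I, label))
        while t < t_phase - _EPS:
            if in_contraction:
                # A-band frozen; actin grows at v_actin_c toward the wall
                cap = p.L_I_min + L_A
                if p.v_actin_c > _EPS and L_actin < cap - _EPS:
                    t_ev = min(t + (cap - L_actin) / p.v_actin_c, t_phase)
                else:
                    t_ev = t_phase
                L_actin = min(cap, L_actin + p.v_actin_c * (t_ev - t))
            else:
                r_a, r_A = _relaxation_rates(p, L_actin, L_A)
                dt_ev = _next_relaxation_event(p, L_actin, L_A, r_a, r_A)
                t_ev = min(t + dt_ev, t_phase)
                L_actin += r_a * (t_ev - t)
                L_A += r_A * (t_ev - t)
            t = t_ev
            if t < t_phase - _EPS:  # interior cap/constraint event
                traj.states.append(SarcomereState(t, L_actin, L_A, L_I, label))
    # closing record at total_time (start-of-phase records cover boundaries)
    last = traj.states[-1]
    if last.t < p.total_time - _EPS:
        traj.states.append(
            SarcomereState(p.total_time, L_actin, L_A, last.L_I_band, last.phase)
        )
    return traj


def time_to_converge(params: ModelParams) -> float:
    """A total_time after which a periodic-schedule run has provably reached
    the fixed point (growth only happens during relaxation fractions)."""
    p = params
    if p.v_actin_r <= 0 or p.v_A_r <= 0:
        raise ValueError("convergence requires positive relaxation growth rates")
    fp = fixed_point(p)
    # with coupled caps each length grows at least at min(v_actin_r, v_A_r)
    # whenever it is below its fixed-point value, and only during relaxation
    gap = max(0.0, fp.L_actin_inf - p.L_actin_0) + max(0.0, fp.L_A_inf - p.L_A_0)
    need = gap / min(p.v_actin_r, p.v_A_r)
    if p.contraction_schedule == "periodic":
        need /= p.T_r / (p.T_r + p.T_c)
    return need + 4.0 * (p.T_r + p.T_c)


@dataclass
class PhaseDiagramGrid:
    """Final lengths and qualitative sarcomere class on an (alpha, L_I_max) grid."""

    alpha_values: np.ndarray
    L_I_max_values: np.ndarray
    L_actin: np.ndarray  # shape (len(L_I_max), len(alpha))
    L_A_band: np.ndarray
    sarcomere_length: np.ndarray
    classification: np.ndarray  # object array of str
    errors: np.ndarray  # bool mask of failed cells


def classify_sarcomere(
    L_I_relaxed: float,
    L_A: float,
    L_actin: float,
    flight_i_frac: float = 0.1,
    flight_overlap_frac: float = 0.9,
    crawling_i_frac: float = 0.5,
) -> str:
    """Qualitative regime from relaxed-state geometry.

    flight-like: tiny I-band fraction and near-complete actomyosin overlap;
    crawling-like: I-band dominates the sarcomere; otherwise intermediate.
    """
    half = L_I_relaxed + L_A
    i_frac = L_I_relaxed / half if half > 0 else 1.0
    overlap = max(0.0, L_actin - L_I_relaxed)
    overlap_frac = overlap / L_actin if L_actin > 0 else 0.0
    if i_frac < flight_i_frac and overlap_frac > flight_overlap_frac:
        return "flight-like"
    if i_frac > crawling_i_frac:
        return "crawling-like"
    return "intermediate"


def phase_diagram(
    alpha_values: Sequence[float],
    L_I_max_values: Sequence[float],
    base_params: ModelParams,
    run_to_convergence: bool = True,
) -> PhaseDiagramGrid:
    """Sweep contraction-set overlap alpha and relaxed I-band length.

    Each cell is a completed simulation (run long enough to converge by
    default); failed cells are flagged, the grid is still returned.
    """
    alphas = np.asarray(list(alpha_values), dtype=float)
    limaxes = np.asarray(list(L_I_max_values), dtype=float)
    if alphas.size == 0 or limaxes.size == 0:
        raise ValueError("phase-diagram grids must be non-empty")
    shape = (limaxes.size, alphas.size)
    la = np.full(shape, np.nan)
    lab = np.full(shape, np.nan)
    sarc = np.full(shape, np.nan)
    cls = np.empty(shape, dtype=object)
    err = np.zeros(shape, dtype=bool)
    for i, limax in enumerate(limaxes):
        for j, a in enumerate(alphas):
            try:
                p = replace(base_params, L_I_max=float(limax), alpha=float(a))
                if run_to_convergence:
                    p = replace(p, total_time=time_to_converge(p))
                final = simulate(p).final
                la[i, j] = final.L_actin
                lab[i, j] = final.L_A_band
                sarc[i, j] = p.sarcomere_factor * (p.L_I_max + final.L_A_band)
                cls[i, j] = classify_sarcomere(p.L_I_max, final.L_A_band,
                                               final.L_actin)
            except (ValueError, ArithmeticError):
                err[i, j] = True
                cls[i, j] = "error"
    return PhaseDiagramGrid(alphas, limaxes, la, lab, sarc, cls, err)


SCENARIO_NAMES = (
    "wild_type",
    "flight_development",
    "hypercontractile",
    "silenced",
    "stiff_cuticle",
)


def scenario(name: str) -> ModelParams:
    """Documented parameter presets for the qualitative regimes.

    All presets share growth rates and elastic parameters and differ only
    in the contraction schedule or relaxed I-band length, so paired runs at
    equal total time isolate one mechanism each:

    * ``wild_type`` — periodic contraction/relaxation cycling.
    * ``silenced`` — contractions blocked entirely; filaments grow for the
      whole run and end up longer than wild type.
    * ``hypercontractile`` — relaxation phases cut short (excessive
      contractions); filaments end up shorter than wild type.
    * ``flight_development`` — spontaneous contractions stop partway
      through the run, as in pupal flight-muscle development; the long
      uninterrupted growth phase yields near-complete actomyosin overlap.
    * ``stiff_cuticle`` — shorter relaxed I-band (a stiffer mechanical
      environment reduces the stretch of titin), instructing shorter
      filaments.
    """
    base = dict(
        L_I_max=2.0,
        T_motor=1.5,
        K_titin=1.0,  # L_I_min = 0.5
        alpha=1.5,
        T_c=1.0,
        T_r=1.0,
        v_actin_r=0.02,
        v_A_r=0.02,
        v_actin_c=0.0,
        L_actin_0=0.6,
        L_A_0=0.3,
        total_time=100.0,
    )
    if name == "wild_type":
        return ModelParams(**base)
    if name == "silenced":
        return ModelParams(**{**base, "contraction_schedule": "none"})
    if name == "hypercontractile":
        return ModelParams(**{**base, "T_r": 0.25, "T_c": 1.75})
    if name == "flight_development":
        return ModelParams(**{**base, "stop_contractions_after": 50.0})
    if name == "stiff_cuticle":
        # shorter relaxed I-band at the same compressed length L_I_min
        return ModelParams(**{**base, "L_I_max": 1.2, "T_motor": 0.7})
    raise ValueError(
        f"unknown scenario {name!r}; choose from {', '.join(SCENARIO_NAMES)}"
    )
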