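"""Quasi-steady-state carrier-cycle transport model.

A single membrane carrier binds amino acid substrates at either face of the
membrane (rapid-equilibrium binding with dissociation constant ``K`` per
substrate), translocates when loaded, and — depending on the relative
mobility ``h`` of the unbound carrier — may also translocate empty.  ``h = 0``
is an obligate exchanger (antiport, strict 1:1 counter-transport); ``h > 0``
adds a facilitated-transport (uniport) component that permits net flux down a
concentration gradient.

Under the quasi-steady-state assumption the carrier distribution between the
two faces equilibrates instantaneously relative to the substrate pools, which
reduces the carrier cycle to a single algebraic flux law integrated over the
pool concentrations in the two compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FACE_EXT",
    "FACE_INT",
    "CarrierParams",
    "AssayState",
    "FaceOccupancy",
    "TimeCourse",
    "OvershootMetrics",
    "face_occupancy",
    "carrier_distribution",
    "net_flux",
    "simulate_uptake",
    "overshoot_metrics",
]

#: Face labels: ``ext`` is the extravesicular (outside) face, ``int`` the
#: intravesicular (inside) face of the membrane.
FACE_EXT = "ext"
FACE_INT = "int"


@dataclass(frozen=True)
class CarrierParams:
    """Kinetic parameters of one carrier.

    Parameters
    ----------
    V : float
        Effective maximal transport rate in µM/min, expressed on the
        intravesicular-concentration scale: ``V = D * T / v_in`` where ``D``
        is the loaded-carrier translocation rate and ``T`` the total carrier
        amount.  ``D`` and ``T`` are not separately identifiable from uptake
        data, so they are lumped.
    h : float
        Relative mobility of the unbound carrier — the translocation rate of
        the empty carrier divided by that of the loaded carrier.  ``h = 0``
        encodes the obligate-exchange variant.
    K : mapping substrate-id -> float
        Dissociation constant in µM per substrate.  A radiolabeled tracer and
        the unlabeled pool of the same chemical species share one ``K``
        (supply the same value under both ids).  ``math.inf`` marks a
        non-substrate (never binds).
    """

    V: float
    h: float
    K: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        for s, k in self.K.items():
            if not k > 0:
                raise ValueError(f"K[{s!r}] must be > 0, got {k}")

    @property
    def is_obligate(self) -> bool:
        return self.h == 0.0


@dataclass
class AssayState:
    """Substrate concentrations in the two compartments plus volumes.

    ``conc`` maps ``(substrate_id, face)`` to a concentration in µM, with
    faces :data:`FACE_EXT` and :data:`FACE_INT`.  Tracer and unlabeled pools
    of the same species carry distinct ids.  Volumes are in µl.
    """

    conc: dict
    v_in: float
    v_out: float

    def __post_init__(self) -> None:
        if not self.v_in > 0:
            raise ValueError(f"v_in must be > 0, got {self.v_in}")
        if not self.v_out > 0:
            raise ValueError(f"v_out must be > 0, got {self.v_out}")
        for (s, face), c in self.conc.items():
            if face not in (FACE_EXT, FACE_INT):
                raise ValueError(f"unknown face {face!r} for substrate {s!r}")
            if c < 0:
                raise ValueError(f"negative concentration for ({s!r}, {face!r}): {c}")

    @property
    def substrates(self) -> tuple:
        seen: dict = {}
        for (s, _face) in self.conc:
            seen.setdefault(s, None)
        return tuple(seen)

    def at_face(self, face: str) -> dict:
        return {s: self.conc.get((s, face), 0.0) for s in self.substrates}

    def swapped(self) -> "AssayState":
        """The state with the two faces (and volumes) interchanged."""
        flip = {FACE_EXT: FACE_INT, FACE_INT: FACE_EXT}
        return AssayState(
            conc={(s, flip[f]): c for (s, f), c in self.conc.items()},
            v_in=self.v_out,
            v_out=self.v_in,
        )


@dataclass(frozen=True)
class FaceOccupancy:
    """Fractional carrier occupancy at one membrane face.

    ``p[s]`` is the fraction of carrier at this face bound to substrate ``s``
    under rapid-equilibrium binding; ``p0`` is the free fraction.  By
    construction ``p0 + sum(p.values()) == 1``.
    """

    p: Mapping[str, float]
    p0: float

    @property
    def loaded(self) -> float:
        return 1.0 - self.p0


def face_occupancy(conc: Mapping[str, float], K: Mapping[str, float]) -> FaceOccupancy:
    """Rapid-equilibrium carrier occupancy at one face.

    ``p[s] = (c_s/K_s) / (1 + sum_j c_j/K_j)`` and
    ``p0 = 1 / (1 + sum_j c_j/K_j)``.
    """
    total = 0.0
    ratios = {}
    for s, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {s!r}: {c}")
        k = K.get(s, math.inf)
        if not k > 0:
            raise ValueError(f"K[{s!r}] must be > 0, got {k}")
        r = c / k
        ratios[s] = r
        total += r
    p0 = 1.0 / (1.0 + total)
    return FaceOccupancy(p={s: r * p0 for s, r in ratios.items()}, p0=p0)


def carrier_distribution(
    occ_ext: FaceOccupancy, occ_int: FaceOccupancy, h: float
) -> tuple:
    """Quasi-steady-state carrier distribution between the two faces.

    Balances the rates of departure from each face:
    ``theta_ext * (L_ext + h*p0_ext) = theta_int * (L_int + h*p0_int)`` with
    ``theta_ext + theta_int = 1``.  When both departure rates vanish (obligate
    carrier facing empty solutions) the split is (0.5, 0.5) by convention —
    the flux is zero either way.
    """
    if h < 0:
        raise ValueError(f"h must be >= 0, got {h}")
    exit_ext = occ_ext.loaded + h * occ_ext.p0
    exit_int = occ_int.loaded + h * occ_int.p0
    denom = exit_ext + exit_int
    if denom == 0.0:
        return 0.5, 0.5
    theta_ext = exit_int / denom
    return theta_ext, 1.0 - theta_ext


def net_flux(state: AssayState, params: CarrierParams) -> dict:
    """Net transport rate for each substrate, µM/min on the intravesicular scale.

    ``d c_{s,int}/dt = V * (theta_ext * p_{s,ext} - theta_int * p_{s,int})``;
    the extravesicular pool changes by ``-(v_in/v_out)`` times that rate.
    Antisymmetric under swapping the two faces (symmetric carrier).
    """
    occ_ext = face_occupancy(state.at_face(FACE_EXT), params.K)
    occ_int = face_occupancy(state.at_face(FACE_INT), params.K)
    theta_ext, theta_int = carrier_distribution(occ_ext, occ_int, params.h)
    return {
        s: params.V * (theta_ext * occ_ext.p[s] - theta_int * occ_int.p[s])
        for s in state.substrates
    }


@dataclass
class TimeCourse:
    """Simulated concentrations on a time grid.

    ``conc`` has shape ``(len(times), 2 * n_substrates)``; the first
    ``n_substrates`` columns are extravesicular, the rest intravesicular,
    ordered as ``substrates``.
    """

    times: np.ndarray
    conc: np.ndarray
    substrates: tuple
    v_in: float
    v_out: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (self.times.size, 2 * len(self.substrates)):
            raise ValueError("conc shape does not match times/substrates")

    def _col(self, substrate: str, face: str) -> int:
        i = self.substrates.index(substrate)
        return i if face == FACE_EXT else i + len(self.substrates)

    def trace(self, substrate: str, face: str = FACE_INT) -> np.ndarray:
        """Concentration time series (µM) of one substrate at one face."""
        return self.conc[:, self._col(substrate, face)]

    def state_at(self, index: int) -> AssayState:
        n = len(self.substrates)
        row = self.conc[index]
        conc = {}
        for i, s in enumerate(self.substrates):
            conc[(s, FACE_EXT)] = float(max(row[i], 0.0))
            conc[(s, FACE_INT)] = float(max(row[i + n], 0.0))
        return AssayState(conc=conc, v_in=self.v_in, v_out=self.v_out)

    def total_amount(self, substrate: str) -> np.ndarray:
        """Total amount of one species over both compartments (µM·µl = pmol)."""
        return (
            self.trace(substrate, FACE_EXT) * self.v_out
            + self.trace(substrate, FACE_INT) * self.v_in
        )


def _pack_state(state: AssayState) -> tuple:
    subs = state.substrates
    n = len(subs)
    y0 = np.empty(2 * n)
    for i, s in enumerate(subs):
        y0[i] = state.conc.get((s, FACE_EXT), 0.0)
        y0[i + n] = state.conc.get((s, FACE_INT), 0.0)
    return subs, y0


def _k_array(substrates: Sequence[str], K: Mapping[str, float]) -> np.ndarray:
    return np.array([K.get(s, math.inf) for s in substrates], dtype=float)


def _qssa_rhs(t, y, Karr, V, h, vratio):
    """Pooled QSSA equations, numpy form (scipy engine and reference)."""
    n = Karr.size
    r = np.maximum(y, 0.0).reshape(2, n) / Karr
    s_ext, s_int = r.sum(axis=1)
    p0_ext = 1.0 / (1.0 + s_ext)
    p0_int = 1.0 / (1.0 + s_int)
    exit_ext = (1.0 - p0_ext) + h * p0_ext
    exit_int = (1.0 - p0_int) + h * p0_int
    denom = exit_ext + exit_int
    theta_ext = exit_int / denom if denom > 0.0 else 0.5
    theta_int = 1.0 - theta_ext
    flux = V * (theta_ext * r[0] * p0_ext - theta_int * r[1] * p0_int)
    return np.concatenate((-vratio * flux, flux))


class IntegrationError(RuntimeError):
    """Raised when time-course integration fails (never silently truncated)."""


def simulate_uptake(
    initial: AssayState,
    params: CarrierParams,
    times: Iterable[float],
    *,
    engine: str = "compiled",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeCourse:
    """Integrate the coupled substrate pools in both compartments.

    Parameters
    ----------
    initial : AssayState
        Concentrations and compartment volumes at ``t = 0``.
    params : CarrierParams
        Carrier kinetics; every substrate in ``initial`` without an entry in
        ``params.K`` is treated as a non-substrate (``K = inf``).
    times : array-like of float
        Output grid in minutes; must start at 0 and be strictly increasing.
    engine : {"compiled", "scipy"}
        "compiled" uses the numba Dormand–Prince kernel, "scipy" uses
        :func:`scipy.integrate.solve_ivp` (LSODA).  The two agree to solver
        tolerance; the compiled kernel is the fast default.

    The overshoot peak height is sensitive to integration accuracy, hence the
    tight default tolerances.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or times[0] != 0.0:
        raise ValueError("times must start at 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")

    subs, y0 = _pack_state(initial)
    Karr = _k_array(subs, params.K)
    vratio = initial.v_in / initial.v_out

    if times.size == 1:
        return TimeCourse(times, y0[None, :].copy(), subs, initial.v_in, initial.v_out)

    if engine == "compiled":
        from ._kernels import integrate_qssa

        sol, status = integrate_qssa(
            y0, Karr, params.V, params.h, vratio, times, rtol, atol
        )
        if status != 0:
            raise IntegrationError(
                f"compiled integrator failed (status={status}) for "
                f"params V={params.V}, h={params.h}; try engine='scipy'"
            )
    elif engine == "scipy":
        from scipy.integrate import solve_ivp

        res = solve_ivp(
            _qssa_rhs,
            (times[0], times[-1]),
            y0,
            t_eval=times,
            args=(Karr, params.V, params.h, vratio),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not res.success:
            raise IntegrationError(f"solve_ivp failed: {res.message}")
        sol = res.y.T
    else:
        raise ValueError(f"unknown engine {engine!r}")

    # Tolerance-level negative excursions are clipped; anything larger is a bug.
    if sol.min() < -1e3 * atol - 1e-6:
        raise IntegrationError(f"negative concentrations in solution: min={sol.min()}")
    sol = np.maximum(sol, 0.0)
    sol[0] = y0
    return TimeCourse(times, sol, subs, initial.v_in, initial.v_out)


@dataclass(frozen=True)
class OvershootMetrics:
    """Summary of transient accumulation above the final level."""

    peak_value: float
    peak_time: float
    final_value: float
    ratio: float
    is_overshoot: bool


def overshoot_metrics(
    tc: TimeCourse,
    substrate: str = "tracer",
    *,
    threshold: float = 0.05,
) -> OvershootMetrics:
    """Detect an overshoot in the intravesicular trace of one substrate.

    The trace overshoots if its maximum exceeds its final value by more than
    ``threshold`` (relative, default 5%).  Constant or empty traces report
    ``ratio = 1`` and no overshoot.
    """
    trace = tc.trace(substrate, FACE_INT)
    if trace.size == 0 or np.ptp(trace) == 0.0:
        final = float(trace[-1]) if trace.size else 0.0
        return OvershootMetrics(final, 0.0, final, 1.0, False)
    i = int(np.argmax(trace))
    peak = float(trace[i])
    final = float(trace[-1])
    ratio = peak / final if final > 0 else math.inf
    return OvershootMetrics(
        peak_value=peak,
        peak_time=float(tc.times[i]),
        final_value=final,
        ratio=ratio,
        is_overshoot=bool(peak > final * (1.0 + threshold)),
    )
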