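"""Full mass-action carrier-cycle model.

This is the unreduced six-state (2 + 2·n_substrates carrier states plus free
pools) system: explicit binding/unbinding at each face with rate constants
``k_on``/``k_off`` (``k_off = k_on * K``), translocation of loaded complexes
at rate ``d`` and of the empty carrier at rate ``h * d``.  It serves as the
independent validation oracle for the quasi-steady-state reduction in
:mod:`carrierflux.model`: in the fast-binding limit (``k_off >> d``) and with
total carrier small relative to the substrate pools, the two agree on the
intravesicular tracer trace.

The system is stiff (binding is orders of magnitude faster than pool
turnover), so it is integrated with scipy's implicit solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    FACE_EXT,
    FACE_INT,
    AssayState,
    CarrierParams,
    IntegrationError,
    TimeCourse,
    carrier_distribution,
    face_occupancy,
)

__all__ = ["FullKineticState", "full_kinetic_state", "full_ode_oracle", "OracleResult"]


@dataclass
class FullKineticState:
    """Complete mass-action state and rate constants.

    Amount-like quantities (carrier and complexes) are in µM·µl (= pmol);
    free pools are concentrations in µM.  ``k_on`` is in µM⁻¹·min⁻¹ and is
    shared across substrates; per-substrate ``k_off = k_on * K``.  ``d`` is
    the loaded-carrier translocation rate (min⁻¹); the empty carrier moves at
    ``h * d``.
    """

    substrates: tuple
    free_ext: np.ndarray  # µM
    free_int: np.ndarray  # µM
    x_ext: float  # free carrier at the outside face, pmol
    x_int: float  # free carrier at the inside face, pmol
    cplx_ext: np.ndarray  # carrier-substrate complexes, pmol
    cplx_int: np.ndarray
    K: np.ndarray  # µM
    k_on: float
    d: float
    h: float
    v_in: float
    v_out: float

    def __post_init__(self) -> None:
        self.free_ext = np.asarray(self.free_ext, dtype=float)
        self.free_int = np.asarray(self.free_int, dtype=float)
        self.cplx_ext = np.asarray(self.cplx_ext, dtype=float)
        self.cplx_int = np.asarray(self.cplx_int, dtype=float)
        n = len(self.substrates)
        for name in ("free_ext", "free_int", "cplx_ext", "cplx_int", "K"):
            if np.asarray(getattr(self, name)).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if self.x_ext < 0 or self.x_int < 0 or (self.cplx_ext < 0).any() or (self.cplx_int < 0).any():
            raise ValueError("carrier amounts must be >= 0")

    @property
    def total_carrier(self) -> float:
        return float(self.x_ext + self.x_int + self.cplx_ext.sum() + self.cplx_int.sum())


def full_kinetic_state(
    state: AssayState,
    params: CarrierParams,
    *,
    d: float = 1e4,
    fast_binding_factor: float = 1e3,
) -> FullKineticState:
    """Build a mass-action state matched to a QSSA ``(state, params)`` pair.

    ``V = d * T / v_in`` fixes the total carrier ``T`` once a translocation
    rate ``d`` is chosen; larger ``d`` means less carrier and a closer QSSA
    correspondence.  ``k_on`` is set so the *slowest* unbinding rate is
    ``fast_binding_factor`` times ``d`` (the fast-binding regime).  The
    carrier starts on its quasi-steady-state distribution with
    rapid-equilibrium occupancies, and the substrate bound in complexes is
    debited from the free pools so species totals match the QSSA setup
    exactly.
    """
    subs = state.substrates
    K = np.array([params.K.get(s, np.inf) for s in subs], dtype=float)
    finite = K[np.isfinite(K)]
    if finite.size == 0:
        raise ValueError("at least one substrate must have a finite K")
    k_on = fast_binding_factor * d / finite.min()
    T = params.V * state.v_in / d  # pmol

    occ_ext = face_occupancy(state.at_face(FACE_EXT), params.K)
    occ_int = face_occupancy(state.at_face(FACE_INT), params.K)
    th_ext, th_int = carrier_distribution(occ_ext, occ_int, params.h)

    cplx_ext = np.array([T * th_ext * occ_ext.p[s] for s in subs])
    cplx_int = np.array([T * th_int * occ_int.p[s] for s in subs])
    free_ext = np.array([state.conc.get((s, FACE_EXT), 0.0) for s in subs])
    free_int = np.array([state.conc.get((s, FACE_INT), 0.0) for s in subs])
    free_ext = np.maximum(free_ext - cplx_ext / state.v_out, 0.0)
    free_int = np.maximum(free_int - cplx_int / state.v_in, 0.0)

    return FullKineticState(
        substrates=subs,
        free_ext=free_ext,
        free_int=free_int,
        x_ext=T * th_ext * occ_ext.p0,
        x_int=T * th_int * occ_int.p0,
        cplx_ext=cplx_ext,
        cplx_int=cplx_int,
        K=K,
        k_on=k_on,
        d=d,
        h=params.h,
        v_in=state.v_in,
        v_out=state.v_out,
    )


@dataclass
class OracleResult:
    """Mass-action trajectory with carrier states retained."""

    times: np.ndarray
    substrates: tuple
    free_ext: np.ndarray  # (m, n) µM
    free_int: np.ndarray  # (m, n) µM
    x_ext: np.ndarray  # (m,) pmol
    x_int: np.ndarray
    cplx_ext: np.ndarray  # (m, n) pmol
    cplx_int: np.ndarray
    v_in: float = 0.0
    v_out: float = 0.0

    def trace(self, substrate: str, face: str = FACE_INT) -> np.ndarray:
        """Free-pool concentration trace (µM) of one substrate."""
        i = self.substrates.index(substrate)
        return (self.free_int if face == FACE_INT else self.free_ext)[:, i]

    def total_carrier(self) -> np.ndarray:
        return self.x_ext + self.x_int + self.cplx_ext.sum(axis=1) + self.cplx_int.sum(axis=1)

    def total_amount(self, substrate: str) -> np.ndarray:
        """Species total over pools and complexes (pmol); conserved."""
        i = self.substrates.index(substrate)
        return (
            self.free_ext[:, i] * self.v_out
            + self.free_int[:, i] * self.v_in
            + self.cplx_ext[:, i]
            + self.cplx_int[:, i]
        )

    def timecourse(self) -> TimeCourse:
        return TimeCourse(
            self.times,
            np.hstack([self.free_ext, self.free_int]),
            self.substrates,
            self.v_in,
            self.v_out,
        )


def full_ode_oracle(
    fks: FullKineticState,
    times: Iterable[float],
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> OracleResult:
    """Integrate the mass-action system exactly on the output grid.

    State layout: ``[free_ext (µM), free_int (µM), cplx_ext (pmol),
    cplx_int (pmol), x_ext, x_int]``.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or times[0] != 0.0:
        raise ValueError("times must start at 0")
    n = len(fks.substrates)
    K = fks.K
    k_on, d, h = fks.k_on, fks.d, fks.h
    hd = h * d
    v_in, v_out = fks.v_in, fks.v_out
    # per-substrate k_off; infinite K = non-binder (k_on forced to 0 via rate)
    k_off = np.where(np.isfinite(K), k_on * K, 0.0)
    bind_scale = np.where(np.isfinite(K), 1.0, 0.0)

    def rhs(t, y):
        a_ext = y[:n]
        a_int = y[n : 2 * n]
        c_ext = y[2 * n : 3 * n]
        c_int = y[3 * n : 4 * n]
        x_ext, x_int = y[4 * n], y[4 * n + 1]
        bind_ext = bind_scale * k_on * np.maximum(a_ext, 0.0) * max(x_ext, 0.0) - k_off * c_ext
        bind_int = bind_scale * k_on * np.maximum(a_int, 0.0) * max(x_int, 0.0) - k_off * c_int
        trans = d * (c_ext - c_int)  # loaded translocation out->in
        dx = hd * (x_int - x_ext)  # empty translocation in->out balance
        dy = np.empty_like(y)
        dy[:n] = -bind_ext / v_out
        dy[n : 2 * n] = -bind_int / v_in
        dy[2 * n : 3 * n] = bind_ext - trans
        dy[3 * n : 4 * n] = bind_int + trans
        dy[4 * n] = -bind_ext.sum() + dx
        dy[4 * n + 1] = -bind_int.sum() - dx
        return dy

    y0 = np.concatenate(
        [fks.free_ext, fks.free_int, fks.cplx_ext, fks.cplx_int, [fks.x_ext, fks.x_int]]
    )
    if times.size == 1:
        Y = y0[None, :]
        return OracleResult(
            times=times,
            substrates=fks.substrates,
            free_ext=Y[:, :n].copy(),
            free_int=Y[:, n : 2 * n].copy(),
            cplx_ext=Y[:, 2 * n : 3 * n].copy(),
            cplx_int=Y[:, 3 * n : 4 * n].copy(),
            x_ext=Y[:, 4 * n],
            x_int=Y[:, 4 * n + 1],
            v_in=v_in,
            v_out=v_out,
        )
    res = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not res.success:
        raise IntegrationError(f"mass-action integration failed: {res.message}")
    Y = res.y.T
    return OracleResult(
        times=times,
        substrates=fks.substrates,
        free_ext=np.maximum(Y[:, :n], 0.0),
        free_int=np.maximum(Y[:, n : 2 * n], 0.0),
        cplx_ext=Y[:, 2 * n : 3 * n],
        cplx_int=Y[:, 3 * n : 4 * n],
        x_ext=Y[:, 4 * n],
        x_int=Y[:, 4 * n + 1],
        v_in=v_in,
        v_out=v_out,
    )
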