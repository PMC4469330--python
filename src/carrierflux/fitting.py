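"""Simultaneous least-squares fitting and model discrimination.

Both model variants are fitted to all conditions at once with a single
global parameter set, on the intravesicular concentration (µM) scale:

* **mixed** — free parameters (h, V, K); the carrier has both an exchange
  and a facilitated component.
* **obligate** — h pinned to 0; free parameters (V, K, endo_int), where
  ``endo_int`` is an initial intravesicular unlabeled substrate
  concentration added to every condition's nominal preload (endogenous
  substrate would be present in every preparation, so condition 1 starts at
  ``endo_int`` and condition 3 at ``250 + endo_int``).

Optimization is bounded trust-region least squares (scipy) from a fixed
log-spaced multistart grid — reproducibility over stochastic exploration.
V and K are searched in log10 space; h and endo_int stay linear because
their lower bounds are 0.  Model discrimination compares the two variants by
R² computed about the grand mean of all fitted points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .design import (
    SUBSTRATE_ID,
    TRACER_ID,
    ConditionMatrix,
    initial_state,
    uptake_to_conc,
)
from .model import FACE_INT, CarrierParams, IntegrationError, simulate_uptake
from .synth import UptakeDataset

__all__ = [
    "FitSpec",
    "FitResult",
    "DiscriminationReport",
    "FittingError",
    "loss",
    "fit",
    "r_squared",
    "discriminate",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = {
    "h": (0.0, 10.0),
    "V": (0.1, 1e4),  # µM/min
    "K": (1.0, 1e5),  # µM
    "endo_int": (0.0, 1e3),  # µM
}

_PENALTY = 1e6  # residual magnitude returned when a simulation fails in-bounds


class FittingError(RuntimeError):
    """Raised when every multistart attempt fails; carries per-start details."""

    def __init__(self, message: str, diagnostics: Optional[list] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one fit.

    ``variant`` selects the free-parameter set; ``multistart`` the number of
    deterministic log-spaced starting points; ``weighting`` either ordinary
    least squares ("none", the default — matching a plain least-squares
    criterion) or inverse-sem² weighting ("sem").
    """

    variant: str = "mixed"
    bounds: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    multistart: int = 8
    weighting: str = "none"
    tracer_id: str = TRACER_ID
    substrate_id: str = SUBSTRATE_ID
    engine: str = "compiled"

    def __post_init__(self) -> None:
        if self.variant not in ("mixed", "obligate"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.weighting not in ("none", "sem"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")

    @property
    def free_parameters(self) -> tuple:
        return ("h", "V", "K") if self.variant == "mixed" else ("V", "K", "endo_int")


@dataclass
class FitResult:
    """Best fit over all starting points."""

    variant: str
    params: dict  # h, V, K (+ endo_int for the obligate variant), natural units
    ssr: float  # µM²
    r2: float
    stderr: dict  # approximate standard errors from the least-squares curvature
    n_obs: int
    best_start: int
    start_ssrs: list
    nfev: int
    success: bool

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params,
            "ssr": self.ssr,
            "r2": self.r2,
            "stderr": self.stderr,
            "n_obs": self.n_obs,
            "best_start": self.best_start,
            "start_ssrs": self.start_ssrs,
            "nfev": self.nfev,
            "success": self.success,
        }


def _prepare(dataset: UptakeDataset, matrix: ConditionMatrix, spec: FitSpec):
    """Group observations by condition; convert uptake to µM once."""
    known = set(matrix.ids)
    groups = []
    obs_all = []
    w_all = []
    for cid in dataset.conditions:
        if cid not in known:
            raise ValueError(f"dataset condition {cid!r} not in the matrix {matrix.ids}")
        sel = dataset.data[dataset.data["condition_id"].astype(str) == cid].sort_values("time_min")
        times = sel["time_min"].to_numpy(dtype=float)
        cond = matrix.get(cid)
        obs = uptake_to_conc(
            sel["mean_uptake_pmol_per_mg"].to_numpy(dtype=float), cond.mix.vol_per_mg
        )
        if spec.weighting == "sem":
            sem = uptake_to_conc(sel["sem"].to_numpy(dtype=float), cond.mix.vol_per_mg)
            if (sem <= 0).any():
                raise ValueError("inverse-sem weighting requires strictly positive sem")
            w = 1.0 / sem
        else:
            w = np.ones_like(obs)
        groups.append((cond, times))
        obs_all.append(obs)
        w_all.append(w)
    return groups, np.concatenate(obs_all), np.concatenate(w_all)


def _model_values(params: Mapping[str, float], groups, spec: FitSpec) -> np.ndarray:
    carrier = CarrierParams(
        V=params["V"],
        h=params.get("h", 0.0),
        K={spec.tracer_id: params["K"], spec.substrate_id: params["K"]},
    )
    endo = params.get("endo_int", 0.0)
    out = []
    for cond, times in groups:
        state = initial_state(
            cond, endo_int=endo, tracer_id=spec.tracer_id, substrate_id=spec.substrate_id
        )
        sim_times = np.concatenate([[0.0], times])
        tc = simulate_uptake(state, carrier, sim_times, engine=spec.engine)
        out.append(tc.trace(spec.tracer_id, FACE_INT)[1:])
    return np.concatenate(out)


def loss(
    params: Mapping[str, float],
    dataset: UptakeDataset,
    matrix: ConditionMatrix,
    *,
    spec: Optional[FitSpec] = None,
) -> float:
    """Sum of squared residuals (µM²) of one parameter point, all conditions."""
    spec = spec or FitSpec()
    groups, obs, w = _prepare(dataset, matrix, spec)
    model = _model_values(params, groups, spec)
    return float(np.sum((w * (obs - model)) ** 2))


def _start_points(spec: FitSpec) -> list:
    """Fixed log-spaced multistart grid (never random)."""
    n_lead = max(1, math.ceil(spec.multistart / 4))
    if spec.variant == "mixed":
        lead = np.geomspace(0.005, 2.0, n_lead) if n_lead > 1 else np.array([0.05])
        lead_name = "h"
    else:
        lead = np.geomspace(1.0, 500.0, n_lead) if n_lead > 1 else np.array([20.0])
        lead_name = "endo_int"
    starts = []
    for x in lead:
        for V0 in (10.0, 300.0):
            for K0 in (100.0, 5000.0):
                starts.append({lead_name: float(x), "V": V0, "K": K0})
    return starts[: spec.multistart]


def _to_x(p: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    return np.array(
        [math.log10(p[n]) if n in ("V", "K") else p[n] for n in names], dtype=float
    )


def _from_x(x: np.ndarray, names: Sequence[str]) -> dict:
    return {
        n: (10.0 ** xi if n in ("V", "K") else float(xi)) for n, xi in zip(names, x)
    }


def fit(
    dataset: UptakeDataset,
    matrix: ConditionMatrix,
    spec: Optional[FitSpec] = None,
) -> FitResult:
    """Bounded multistart least squares; deterministic for fixed inputs."""
    spec = spec or FitSpec()
    groups, obs, w = _prepare(dataset, matrix, spec)
    n_cond = len(groups)
    n_times = min(len(t) for _, t in groups)
    if n_cond < 2 or n_times < 3:
        logger.warning(
            "sparse design (%d conditions, >=%d time points); parameters may be "
            "poorly identified",
            n_cond,
            n_times,
        )

    names = spec.free_parameters
    lo = np.array(
        [math.log10(spec.bounds[n][0]) if n in ("V", "K") else spec.bounds[n][0] for n in names]
    )
    hi = np.array(
        [math.log10(spec.bounds[n][1]) if n in ("V", "K") else spec.bounds[n][1] for n in names]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _from_x(x, names)
        try:
            model = _model_values(p, groups, spec)
        except IntegrationError as exc:
            logger.warning("simulation failed at %s: %s", p, exc)
            return np.full(obs.size, _PENALTY)
        return w * (obs - model)

    best = None
    diagnostics = []
    start_ssrs = []
    total_nfev = 0
    for idx, start in enumerate(_start_points(spec)):
        x0 = np.clip(_to_x(start, names), lo, hi)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-13,
                gtol=1e-12,
                diff_step=1e-6,
                max_nfev=500,
            )
        except Exception as exc:  # noqa: BLE001 - collected into diagnostics
            diagnostics.append((idx, start, repr(exc)))
            start_ssrs.append(math.inf)
            continue
        total_nfev += res.nfev
        ssr = float(2.0 * res.cost)
        start_ssrs.append(ssr)
        if best is None or ssr < best[0]:
            best = (ssr, idx, res)
    if best is None:
        raise FittingError("all multistart attempts failed", diagnostics)

    ssr, best_idx, res = best
    params = _from_x(res.x, names)
    if spec.variant == "obligate":
        params["h"] = 0.0

    stderr = _stderr(res, names, ssr, obs.size)
    r2 = r_squared(ssr, obs)
    return FitResult(
        variant=spec.variant,
        params=params,
        ssr=ssr,
        r2=r2,
        stderr=stderr,
        n_obs=int(obs.size),
        best_start=best_idx,
        start_ssrs=start_ssrs,
        nfev=total_nfev,
        success=bool(res.success),
    )


def _stderr(res, names: Sequence[str], ssr: float, n_obs: int) -> dict:
    """Approximate standard errors from the Gauss-Newton curvature.

    The Jacobian is with respect to the internal coordinates; the chain rule
    maps log10-space columns back to natural units (dx/dp = 1/(p ln10)).
    """
    k = len(names)
    dof = max(n_obs - k, 1)
    s2 = ssr / dof
    J = res.jac
    try:
        cov_x = s2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}
    out = {}
    for i, n in enumerate(names):
        var = cov_x[i, i]
        if n in ("V", "K"):
            p = 10.0 ** res.x[i]
            out[n] = float(math.sqrt(max(var, 0.0)) * p * math.log(10.0))
        else:
            out[n] = float(math.sqrt(max(var, 0.0)))
    return out


def r_squared(ssr: float, observed_uM: np.ndarray) -> float:
    """R² about the grand mean of all fitted points; may be negative."""
    observed_uM = np.asarray(observed_uM, dtype=float)
    sst = float(np.sum((observed_uM - observed_uM.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("constant data: R² is undefined (SST = 0)")
    return 1.0 - ssr / sst


@dataclass
class DiscriminationReport:
    """Side-by-side comparison of the two model variants on one dataset."""

    mixed: FitResult
    obligate: FitResult
    delta_r2: float
    delta_ssr: float
    preferred: str

    def to_dict(self) -> dict:
        return {
            "mixed": self.mixed.to_dict(),
            "obligate": self.obligate.to_dict(),
            "delta_r2": self.delta_r2,
            "delta_ssr": self.delta_ssr,
            "preferred": self.preferred,
        }


def discriminate(
    dataset: UptakeDataset,
    matrix: ConditionMatrix,
    *,
    mixed_spec: Optional[FitSpec] = None,
    obligate_spec: Optional[FitSpec] = None,
) -> DiscriminationReport:
    """Fit both variants and prefer the one with the higher R²."""
    mixed_spec = mixed_spec or FitSpec(variant="mixed")
    obligate_spec = obligate_spec or FitSpec(variant="obligate")
    if mixed_spec.variant != "mixed" or obligate_spec.variant != "obligate":
        raise ValueError("specs must carry their respective variants")
    fit_mixed = fit(dataset, matrix, mixed_spec)
    fit_obl = fit(dataset, matrix, obligate_spec)
    return DiscriminationReport(
        mixed=fit_mixed,
        obligate=fit_obl,
        delta_r2=fit_mixed.r2 - fit_obl.r2,
        delta_ssr=fit_mixed.ssr - fit_obl.ssr,
        preferred="mixed" if fit_mixed.r2 > fit_obl.r2 else "obligate",
    )
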