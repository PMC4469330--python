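"""Synthetic uptake datasets with the statistical structure of a vesicle assay.

Each measured point is the mean over a handful of biological replicates
("placentas") of a filter-count converted to pmol tracer per mg membrane
protein.  The generator simulates the carrier model per condition, converts
intravesicular tracer concentration to pmol/mg, and draws i.i.d. Gaussian
replicates (sd = max(floor, cv·value), truncated at zero — scintillation
counting noise acts on the measured uptake scale, not on concentration),
reporting means ± sem.  Between-replicate variation is pure noise; no
hierarchical replicate effect is modeled because downstream fitting operates
on the averaged curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_TRACER_CONC,
    SUBSTRATE_ID,
    TRACER_ID,
    Condition,
    ConditionMatrix,
    MixingScheme,
    conc_to_uptake,
    initial_state,
)
from .model import FACE_INT, CarrierParams, simulate_uptake

__all__ = ["NoiseModel", "UptakeDataset", "DEFAULT_TIMES", "generate_dataset", "generate_preload_panel"]

#: Default sampling grid in minutes (assays run from ~15 s to 10 min).
DEFAULT_TIMES = (0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the synthetic assay.

    ``cv`` is the relative noise fraction per replicate, ``floor`` an
    absolute noise floor in pmol/mg.  ``n_replicates`` fixes the replicate
    count per condition; ``None`` draws it uniformly from 5–9, mimicking the
    varying number of placentas behind each condition.
    """

    cv: float = 0.10
    floor: float = 0.3  # pmol/mg
    n_replicates: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be >= 0")
        if self.n_replicates is not None and self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


NOISELESS = NoiseModel(cv=0.0, floor=0.0, n_replicates=1)


@dataclass
class UptakeDataset:
    """Tidy uptake time-course measurements.

    ``data`` columns: condition_id, time_min, mean_uptake_pmol_per_mg, sem, n.
    ``provenance`` records the generating configuration when synthetic.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    COLUMNS = ("condition_id", "time_min", "mean_uptake_pmol_per_mg", "sem", "n")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset is missing columns: {sorted(missing)}")
        if (self.data["sem"] < 0).any():
            raise ValueError("sem must be >= 0")

    @property
    def conditions(self) -> tuple:
        return tuple(dict.fromkeys(self.data["condition_id"].astype(str)))

    def times_for(self, condition_id: str) -> np.ndarray:
        sel = self.data[self.data["condition_id"].astype(str) == str(condition_id)]
        return np.sort(sel["time_min"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in self.provenance.items():
                fh.write(f"# {key}: {val}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "UptakeDataset":
        provenance = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                body_start = i + 1
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    provenance[key.strip()] = val.strip()
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        df["condition_id"] = df["condition_id"].astype(str)
        return cls(data=df, provenance=provenance)


def _replicate_counts(noise: NoiseModel, n_conditions: int, rng: np.random.Generator) -> np.ndarray:
    if noise.n_replicates is not None:
        return np.full(n_conditions, noise.n_replicates, dtype=int)
    return rng.integers(5, 10, size=n_conditions)


def _noisy_means(curve_pmol: np.ndarray, n: int, noise: NoiseModel, rng: np.random.Generator):
    sd = np.maximum(noise.floor, noise.cv * curve_pmol)
    reps = np.maximum(curve_pmol[None, :] + sd[None, :] * rng.standard_normal((n, curve_pmol.size)), 0.0)
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem


def generate_dataset(
    true_params: CarrierParams,
    matrix: ConditionMatrix,
    times: Iterable[float] = DEFAULT_TIMES,
    noise: NoiseModel = NOISELESS,
    *,
    endo_int: float = 0.0,
    tracer_id: str = TRACER_ID,
    substrate_id: str = SUBSTRATE_ID,
    engine: str = "compiled",
) -> UptakeDataset:
    """Simulate every condition and add replicate-level measurement noise.

    With ``cv = 0`` and ``floor = 0`` the reported means equal the noise-free
    model curve exactly.  Fully reproducible from ``noise.seed``.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or times[0] <= 0:
        raise ValueError("sampling times must be positive (t = 0 is implicit)")
    rng = np.random.default_rng(noise.seed)
    counts = _replicate_counts(noise, len(matrix), rng)

    rows = []
    sim_times = np.concatenate([[0.0], times])
    for cond, n in zip(matrix, counts):
        state = initial_state(
            cond, endo_int=endo_int, tracer_id=tracer_id, substrate_id=substrate_id
        )
        tc = simulate_uptake(state, true_params, sim_times, engine=engine)
        curve_uM = tc.trace(tracer_id, FACE_INT)[1:]
        curve_pmol = conc_to_uptake(curve_uM, cond.mix.vol_per_mg)
        mean, sem = _noisy_means(curve_pmol, int(n), noise, rng)
        for t, m, s in zip(times, mean, sem):
            rows.append((cond.id, t, m, s, int(n)))

    df = pd.DataFrame(rows, columns=list(UptakeDataset.COLUMNS))
    provenance = {
        "generator": "carrierflux.synth.generate_dataset",
        "V": true_params.V,
        "h": true_params.h,
        "K": dict(true_params.K),
        "endo_int": endo_int,
        "cv": noise.cv,
        "floor": noise.floor,
        "n_replicates": noise.n_replicates,
        "seed": noise.seed,
    }
    return UptakeDataset(data=df, provenance=provenance)


def generate_preload_panel(
    substrate_Ks: Mapping[str, float],
    true_params: CarrierParams,
    noise: NoiseModel = NOISELESS,
    *,
    preload_conc: float = 1000.0,
    times: Iterable[float] = DEFAULT_TIMES,
    tracer_ext: float = DEFAULT_TRACER_CONC,
    mix: Optional[MixingScheme] = None,
    tracer_id: str = TRACER_ID,
    engine: str = "compiled",
) -> UptakeDataset:
    """Tracer uptake into vesicles preloaded with different substrates.

    One time course per entry of ``substrate_Ks`` (the preloaded compound and
    its dissociation constant; ``inf`` marks a non-substrate such as an
    osmotic control, which reproduces the non-loaded baseline), plus a
    ``nonloaded`` control.  Substrates with finite K trans-stimulate tracer
    influx; higher affinity (smaller K) at the inside face gives a larger
    overshoot.
    """
    mix = mix or MixingScheme(vol_buffer=380.0)
    times = np.asarray(list(times), dtype=float)
    rng = np.random.default_rng(noise.seed)
    panel = {"nonloaded": None, **dict(substrate_Ks)}
    counts = _replicate_counts(noise, len(panel), rng)

    rows = []
    sim_times = np.concatenate([[0.0], times])
    for (name, kval), n in zip(panel.items(), counts):
        conc = {(tracer_id, "ext"): tracer_ext, (tracer_id, "int"): 0.0}
        K = dict(true_params.K)
        if name != "nonloaded":
            mixres_ext = preload_conc * mix.suspension_fraction
            conc[(name, "ext")] = mixres_ext
            conc[(name, "int")] = preload_conc
            K[name] = kval
        from .model import AssayState

        state = AssayState(conc=conc, v_in=mix.v_in, v_out=mix.v_out)
        params = CarrierParams(V=true_params.V, h=true_params.h, K=K)
        tc = simulate_uptake(state, params, sim_times, engine=engine)
        curve_pmol = conc_to_uptake(tc.trace(tracer_id, FACE_INT)[1:], mix.vol_per_mg)
        mean, sem = _noisy_means(curve_pmol, int(n), noise, rng)
        for t, m, s in zip(times, mean, sem):
            rows.append((name, t, m, s, int(n)))

    df = pd.DataFrame(rows, columns=list(UptakeDataset.COLUMNS))
    return UptakeDataset(
        data=df,
        provenance={
            "generator": "carrierflux.synth.generate_preload_panel",
            "preload_conc": preload_conc,
            "substrate_Ks": dict(substrate_Ks),
            "seed": noise.seed,
        },
    )
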