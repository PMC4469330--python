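"""Serialization: YAML configs, tidy CSV time courses, JSON fit results."""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .design import Condition, ConditionMatrix, MixingScheme, conc_to_uptake
from .fitting import DiscriminationReport, FitResult
from .model import FACE_EXT, FACE_INT, CarrierParams, TimeCourse

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "matrix_to_dict",
    "matrix_from_dict",
    "save_matrix",
    "load_matrix",
    "timecourse_frame",
    "save_fit_result",
    "config_digest",
]


def config_digest(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# -- carrier parameters -----------------------------------------------------

def params_to_dict(params: CarrierParams) -> dict:
    return {"V": params.V, "h": params.h, "K": dict(params.K)}


def params_from_dict(d: Mapping) -> CarrierParams:
    return CarrierParams(V=float(d["V"]), h=float(d["h"]), K={k: float(v) for k, v in d["K"].items()})


def save_params(params: CarrierParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_params(path) -> CarrierParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


# -- condition matrix -------------------------------------------------------

def matrix_to_dict(matrix: ConditionMatrix) -> dict:
    rows = []
    for c in matrix:
        rows.append(
            {
                "id": c.id,
                "ext_uM": c.ext_unlabeled,
                "int_uM": c.int_unlabeled,
                "tracer_uM": c.tracer_ext,
                "preload_uM": c.preload_medium_conc,
                "vol_susp_ul": c.mix.vol_suspension,
                "vol_buffer_ul": c.mix.vol_buffer,
                "protein_mg": c.mix.protein_mass,
                "vol_per_mg": c.mix.vol_per_mg,
                "nominal_mode": c.mix.nominal_mode,
            }
        )
    return {"conditions": rows}


def matrix_from_dict(d: Mapping) -> ConditionMatrix:
    conditions = []
    for row in d["conditions"]:
        mix = MixingScheme(
            vol_suspension=float(row.get("vol_susp_ul", 20.0)),
            vol_buffer=float(row.get("vol_buffer_ul", 20.0)),
            protein_mass=float(row.get("protein_mg", 0.2)),
            vol_per_mg=float(row.get("vol_per_mg", 1.3)),
            nominal_mode=bool(row.get("nominal_mode", True)),
        )
        conditions.append(
            Condition(
                id=str(row["id"]),
                ext_unlabeled=float(row["ext_uM"]),
                int_unlabeled=float(row["int_uM"]),
                tracer_ext=float(row.get("tracer_uM", 7.5)),
                preload_medium_conc=float(row.get("preload_uM", 0.0)),
                mix=mix,
            )
        )
    return ConditionMatrix(conditions)


def save_matrix(matrix: ConditionMatrix, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(matrix_to_dict(matrix), fh, sort_keys=False)


def load_matrix(path) -> ConditionMatrix:
    with open(path) as fh:
        return matrix_from_dict(yaml.safe_load(fh))


# -- time courses -----------------------------------------------------------

def timecourse_frame(
    tc: TimeCourse,
    condition_id: str,
    vol_per_mg: Optional[float] = None,
) -> pd.DataFrame:
    """Tidy long-form table of a simulation.

    Columns: condition_id, time_min, substrate_id, face, conc_uM,
    uptake_pmol_per_mg (intravesicular rows only; NaN outside).
    """
    rows = []
    for s in tc.substrates:
        for face in (FACE_EXT, FACE_INT):
            trace = tc.trace(s, face)
            for t, c in zip(tc.times, trace):
                uptake = (
                    conc_to_uptake(c, vol_per_mg)
                    if (face == FACE_INT and vol_per_mg is not None)
                    else float("nan")
                )
                rows.append((condition_id, t, s, face, c, uptake))
    return pd.DataFrame(
        rows,
        columns=[
            "condition_id",
            "time_min",
            "substrate_id",
            "face",
            "conc_uM",
            "uptake_pmol_per_mg",
        ],
    )


# -- fit results ------------------------------------------------------------

def save_fit_result(
    result,
    path,
    *,
    data_checksum: Optional[str] = None,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a FitResult or DiscriminationReport as JSON with provenance."""
    if isinstance(result, (FitResult, DiscriminationReport)):
        body = result.to_dict()
    else:
        body = dict(result)
    payload = {
        "result": body,
        "provenance": {
            "package": "carrierflux",
            "version": __version__,
            "data_sha256": data_checksum,
            "config_digest": config_digest(config) if config is not None else None,
            "seed": seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
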