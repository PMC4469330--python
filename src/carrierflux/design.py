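"""The 8-condition vesicle uptake experiment: matrix, mixing and units.

Uptake of a radiolabeled tracer (7.5 µM external at t = 0) is measured into
membrane vesicles whose interior and exterior carry chosen concentrations of
the unlabeled form of the same amino acid.  The matrix spans zero-trans
conditions (no internal substrate; conditions 1, 2, 5), trans-stimulation
with an outward gradient (3, 4, 4b) and saturating external substrate
(5, 6, 7).  Conditions 4 and 4b share a 1000 µM preload but dilute the
suspension into different external buffer volumes to set the external
unlabeled concentration to 250 or 50 µM.

Concentrations can be taken at face value as post-mix initial values
("nominal" mode, the default, matching how the conditions are reported) or
recomputed mechanistically from the mixing volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .model import FACE_EXT, FACE_INT, AssayState

__all__ = [
    "MixingScheme",
    "Condition",
    "ConditionMatrix",
    "MixResult",
    "build_matrix",
    "apply_mixing",
    "uptake_to_conc",
    "conc_to_uptake",
    "add_endogenous",
    "initial_state",
    "TRACER_ID",
    "SUBSTRATE_ID",
    "DEFAULT_TRACER_CONC",
    "DEFAULT_VOL_PER_MG",
]

TRACER_ID = "tracer"
SUBSTRATE_ID = "serine"

DEFAULT_TRACER_CONC = 7.5  # µM external tracer at t = 0
DEFAULT_VOL_PER_MG = 1.3  # µl intravesicular volume per mg membrane protein


@dataclass(frozen=True)
class MixingScheme:
    """How a vesicle suspension is combined with external buffer.

    Defaults: 20 µl suspension into 20 µl buffer with 0.2 mg membrane
    protein, intravesicular volume 1.3 µl/mg.  In ``nominal_mode`` the stated
    condition concentrations are taken as post-mix initial values; otherwise
    they are computed from the volumes.
    """

    vol_suspension: float = 20.0  # µl
    vol_buffer: float = 20.0  # µl
    protein_mass: float = 0.2  # mg
    vol_per_mg: float = DEFAULT_VOL_PER_MG  # µl/mg
    nominal_mode: bool = True

    def __post_init__(self) -> None:
        if self.vol_suspension <= 0 or self.vol_buffer <= 0:
            raise ValueError("mixing volumes must be > 0")
        if self.protein_mass <= 0 or self.vol_per_mg <= 0:
            raise ValueError("protein mass and volume per mg must be > 0")
        if self.v_in > self.total_volume:
            raise ValueError("intravesicular volume exceeds total volume")

    @property
    def total_volume(self) -> float:
        return self.vol_suspension + self.vol_buffer

    @property
    def v_in(self) -> float:
        return self.protein_mass * self.vol_per_mg

    @property
    def v_out(self) -> float:
        return self.total_volume - self.v_in

    @property
    def suspension_fraction(self) -> float:
        """Fraction of the final volume contributed by the suspension medium."""
        return self.vol_suspension / self.total_volume


@dataclass(frozen=True)
class Condition:
    """One row of the experimental matrix.

    ``ext_unlabeled`` / ``int_unlabeled`` are the nominal post-mix initial
    unlabeled substrate concentrations (µM) outside and inside the vesicles;
    ``preload_medium_conc`` is the unlabeled substrate concentration of the
    vesicle suspension medium before mixing (used by the mechanistic mode and
    by the endogenous-substrate scenario).
    """

    id: str
    ext_unlabeled: float
    int_unlabeled: float
    tracer_ext: float = DEFAULT_TRACER_CONC
    preload_medium_conc: float = 0.0
    mix: MixingScheme = field(default_factory=MixingScheme)

    def __post_init__(self) -> None:
        for name in ("ext_unlabeled", "int_unlabeled", "tracer_ext", "preload_medium_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class ConditionMatrix:
    """An ordered collection of uniquely-identified conditions."""

    def __init__(self, conditions: Iterable[Condition]):
        self._conditions = list(conditions)
        ids = [c.id for c in self._conditions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate condition ids: {ids}")

    def __iter__(self) -> Iterator[Condition]:
        return iter(self._conditions)

    def __len__(self) -> int:
        return len(self._conditions)

    @property
    def ids(self) -> tuple:
        return tuple(c.id for c in self._conditions)

    def get(self, condition_id: str) -> Condition:
        for c in self._conditions:
            if c.id == condition_id:
                return c
        raise KeyError(f"no condition with id {condition_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": [c.id for c in self],
                "ext_uM": [c.ext_unlabeled for c in self],
                "int_uM": [c.int_unlabeled for c in self],
                "tracer_uM": [c.tracer_ext for c in self],
                "preload_uM": [c.preload_medium_conc for c in self],
                "vol_susp_ul": [c.mix.vol_suspension for c in self],
                "vol_buffer_ul": [c.mix.vol_buffer for c in self],
            }
        )


#: (ext, int, preload, vol_buffer) per condition id; ext/int are the nominal
#: post-mix unlabeled concentrations, preload the suspension-medium value.
_MATRIX_ROWS = (
    ("1", 0.0, 0.0, 0.0, 20.0),
    ("2", 250.0, 0.0, 0.0, 20.0),
    ("3", 250.0, 250.0, 250.0, 20.0),
    ("4", 250.0, 1000.0, 1000.0, 50.0),
    ("4b", 50.0, 1000.0, 1000.0, 380.0),
    ("5", 1000.0, 0.0, 0.0, 20.0),
    ("6", 1000.0, 250.0, 250.0, 20.0),
    ("7", 1000.0, 1000.0, 1000.0, 20.0),
)


def build_matrix(
    *,
    tracer_ext: float = DEFAULT_TRACER_CONC,
    protein_mass: float = 0.2,
    vol_per_mg: float = DEFAULT_VOL_PER_MG,
    vol_suspension: float = 20.0,
    nominal_mode: bool = True,
) -> ConditionMatrix:
    """The standard 8-condition matrix.

    Nominal (ext : int) unlabeled substrate in µM — 1:(0:0), 2:(250:0),
    3:(250:250), 4:(250:1000), 4b:(50:1000), 5:(1000:0), 6:(1000:250),
    7:(1000:1000) — with tracer ``tracer_ext`` external at t = 0.
    """
    conditions = []
    for cid, ext, internal, preload, vol_buffer in _MATRIX_ROWS:
        mix = MixingScheme(
            vol_suspension=vol_suspension,
            vol_buffer=vol_buffer,
            protein_mass=protein_mass,
            vol_per_mg=vol_per_mg,
            nominal_mode=nominal_mode,
        )
        conditions.append(
            Condition(
                id=cid,
                ext_unlabeled=ext,
                int_unlabeled=internal,
                tracer_ext=tracer_ext,
                preload_medium_conc=preload,
                mix=mix,
            )
        )
    return ConditionMatrix(conditions)


@dataclass(frozen=True)
class MixResult:
    ext_initial: float
    int_initial: float
    v_in: float
    v_out: float


def apply_mixing(
    preload_conc: float,
    mix: MixingScheme,
    *,
    buffer_conc: float = 0.0,
) -> MixResult:
    """Dilute a preloaded vesicle suspension into external buffer.

    The suspension medium (at ``preload_conc`` µM) and the buffer (at
    ``buffer_conc`` µM) mix into the external pool; the vesicle interior
    itself is not diluted and stays at ``preload_conc``.  Moles are conserved
    by construction.
    """
    if preload_conc < 0 or buffer_conc < 0:
        raise ValueError("concentrations must be >= 0")
    total = mix.total_volume
    ext_initial = (
        preload_conc * mix.vol_suspension / total + buffer_conc * mix.vol_buffer / total
    )
    return MixResult(
        ext_initial=ext_initial,
        int_initial=preload_conc,
        v_in=mix.v_in,
        v_out=mix.v_out,
    )


def uptake_to_conc(uptake_pmol_per_mg, vol_per_mg: float = DEFAULT_VOL_PER_MG):
    """pmol/mg protein -> intravesicular µM (divide by µl/mg)."""
    if vol_per_mg <= 0:
        raise ValueError("vol_per_mg must be > 0")
    return uptake_pmol_per_mg / vol_per_mg


def conc_to_uptake(conc_uM, vol_per_mg: float = DEFAULT_VOL_PER_MG):
    """Intravesicular µM -> pmol/mg protein (multiply by µl/mg)."""
    if vol_per_mg <= 0:
        raise ValueError("vol_per_mg must be > 0")
    return conc_uM * vol_per_mg


def add_endogenous(matrix: ConditionMatrix, endo_conc: float) -> ConditionMatrix:
    """Add endogenous substrate carried by the vesicle suspension.

    ``endo_conc`` µM of unlabeled substrate is added to the vesicle interior
    and to the suspension medium of every condition; the medium share dilutes
    into the external pool according to each condition's mixing volumes
    (e.g. +150 µM external for a 20+20 µl mix, +15 µM for 20+380 µl).
    """
    if endo_conc < 0:
        raise ValueError("endo_conc must be >= 0")
    if endo_conc == 0:
        return matrix
    out = []
    for c in matrix:
        out.append(
            replace(
                c,
                ext_unlabeled=c.ext_unlabeled + endo_conc * c.mix.suspension_fraction,
                int_unlabeled=c.int_unlabeled + endo_conc,
                preload_medium_conc=c.preload_medium_conc + endo_conc,
            )
        )
    return ConditionMatrix(out)


def initial_state(
    condition: Condition,
    *,
    endo_int: float = 0.0,
    tracer_id: str = TRACER_ID,
    substrate_id: str = SUBSTRATE_ID,
) -> AssayState:
    """The t = 0 :class:`AssayState` for one condition.

    ``endo_int`` adds an unlabeled concentration to the vesicle interior only
    (the free parameter of the obligate-variant fit).  In nominal mode the
    condition's stated concentrations are used directly; in mechanistic mode
    the external values are recomputed from the mixing volumes, treating the
    stated external/tracer values as pre-mix buffer concentrations.
    """
    if endo_int < 0:
        raise ValueError("endo_int must be >= 0")
    mix = condition.mix
    if mix.nominal_mode:
        ext_u = condition.ext_unlabeled
        int_u = condition.int_unlabeled
        tracer = condition.tracer_ext
    else:
        mixed = apply_mixing(
            condition.preload_medium_conc, mix, buffer_conc=condition.ext_unlabeled
        )
        ext_u = mixed.ext_initial
        int_u = mixed.int_initial
        tracer = condition.tracer_ext * mix.vol_buffer / mix.total_volume
    return AssayState(
        conc={
            (tracer_id, FACE_EXT): tracer,
            (tracer_id, FACE_INT): 0.0,
            (substrate_id, FACE_EXT): ext_u,
            (substrate_id, FACE_INT): int_u + endo_int,
        },
        v_in=mix.v_in,
        v_out=mix.v_out,
    )
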