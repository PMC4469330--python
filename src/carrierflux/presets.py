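"""Reference parameter sets for the serine/system-L carrier.

The prediction set (h = 0.04, K = 1129 µM, V = 92 µM/min, intravesicular
volume 1.3 µl/mg) is the parameterization used to generate the a-priori
uptake simulations; h = 0.16 is the value recovered when the mixed model is
fitted to vesicle data, and 10 µM is the endogenous intravesicular serine
the obligate variant needs to explain any zero-trans uptake at all.
"""

from __future__ import annotations

from .design import SUBSTRATE_ID, TRACER_ID
from .model import CarrierParams

__all__ = [
    "PREDICTION_H",
    "PREDICTION_K",
    "PREDICTION_V",
    "FITTED_H",
    "OBLIGATE_ENDO_INT",
    "prediction_params",
]

PREDICTION_H = 0.04
PREDICTION_K = 1129.0  # µM
PREDICTION_V = 92.0  # µM/min
FITTED_H = 0.16
OBLIGATE_ENDO_INT = 10.0  # µM

def prediction_params(
    h: float = PREDICTION_H,
    K: float = PREDICTION_K,
    V: float = PREDICTION_V,
) -> CarrierParams:
    """Carrier parameters with the tracer and unlabeled pools sharing one K."""
    return CarrierParams(V=V, h=h, K={TRACER_ID: K, SUBSTRATE_ID: K})
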