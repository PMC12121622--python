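"""Single entry point for fitting any of the ten model kinds by name."""

from __future__ import annotations

from .data import AnalysisDataset
from .glm import fit_count_glm, fit_logistic
from .mixture import fit_hurdle, fit_zero_inflated
from .model import MODEL_KINDS, FittedModel

__all__ = ["fit_model", "MODEL_KINDS"]

_DISPATCH = {
    "LR": lambda d: fit_logistic(d),
    "PR": lambda d: fit_count_glm(d, "poisson"),
    "RP": lambda d: fit_count_glm(d, "poisson", robust=True),
    "NB": lambda d: fit_count_glm(d, "negbin"),
    "GP": lambda d: fit_count_glm(d, "genpoisson"),
    "ZIP": lambda d: fit_zero_inflated(d, "poisson"),
    "ZIRP": lambda d: fit_zero_inflated(d, "poisson", robust=True),
    "ZINB": lambda d: fit_zero_inflated(d, "negbin"),
    "ZIGP": lambda d: fit_zero_inflated(d, "genpoisson"),
    "ZHP": lambda d: fit_hurdle(d, "poisson"),
    "ZHNB": lambda d: fit_hurdle(d, "negbin"),
}


def fit_model(kind: str, data: AnalysisDataset) -> FittedModel:
    """Fit one of LR, PR, RP, NB, GP, ZIP, ZIRP, ZINB, ZIGP, ZHP, ZHNB."""
    try:
        fitter = _DISPATCH[kind.upper()]
    except KeyError:
        raise ValueError(
            f"unknown model kind {kind!r}; valid kinds: {', '.join(_DISPATCH)}"
        ) from None
    return fitter(data)
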