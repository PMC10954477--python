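"""pH extrapolation of anionic-state populations and exchange rates.

Wobble → anion exchange is a deprotonation: its forward rate (and hence the
anion population) rises with pH while the backward (reprotonation-coupled)
rate is treated as pH-independent, consistent with a late transition state.
Tautomer (ES1) kinetics are pH-independent by construction in this module —
no function here ever rescales an ES1 rate.

Two equivalent extrapolation routes are provided:

* **Rate-slope route** — ``ln k = a·pH + b_i`` with a shared slope *a*
  (default ln 10 per pH unit, i.e. a tenfold rate change per pH unit, as
  expected for hydroxide-mediated deprotonation) and duplex-specific
  intercepts.  A measured rate at one pH maps to another pH through
  ``k → k·exp(a·ΔpH)``.
* **pKa route** — the anion population at any pH follows the
  Henderson–Hasselbalch curve of the apparent pKa,
  ``p_ES2 = 10^(pH−pKa)/(1+10^(pH−pKa))``, and the forward rate is fixed by
  the pH-independent backward rate via
  ``k_GS→ES2 = k_ES2→GS · p_ES2/(1 − p_ES2 − p_ES1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .exceptions import DomainError, ValidationError

__all__ = [
    "DEFAULT_SLOPE",
    "PhModel",
    "extrapolate_anion_population",
    "extrapolate_rate",
    "forward_rate_from_pka",
]

#: d ln(k)/d pH for the anion-forming rates: tenfold per pH unit.
DEFAULT_SLOPE = math.log(10.0)

#: pH window inside which the linear extrapolation is considered trustworthy.
_SAFE_RANGE = (6.0, 9.0)


@dataclass
class PhModel:
    """pH dependence of the anion-forming exchange rates.

    ``slope_a`` is shared across duplexes; ``intercepts`` hold per-duplex,
    per-rate intercepts ``b_i`` of ``ln k = a·pH + b_i``; ``reference_ph``
    and ``reference_rates`` record where the input rates were measured.
    """

    slope_a: float = DEFAULT_SLOPE
    pka_app: float | None = None
    intercepts: dict[str, float] = field(default_factory=dict)
    reference_ph: float | None = None
    reference_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope_a):
            raise ValidationError("slope must be finite")


def _warn_range(ph: float) -> None:
    if not (_SAFE_RANGE[0] <= ph <= _SAFE_RANGE[1]):
        warnings.warn(
            f"pH {ph} outside the validated extrapolation range {_SAFE_RANGE}"
        )


def extrapolate_anion_population(pka_app: float, ph: float) -> float:
    """Anion (ES2) population at a given pH from the apparent pKa.

    ``p_ES2 = 10^(pH − pKa_app) / (1 + 10^(pH − pKa_app))`` — strictly in
    (0, 1), equal to 1/2 at pH = pKa_app.
    """
    if not math.isfinite(pka_app):
        raise ValidationError("pKa_app must be finite")
    x = 10.0 ** (ph - pka_app)
    return x / (1.0 + x)


def extrapolate_rate(
    model: PhModel, rate_label: str, ph_from: float, ph_to: float, k_from: float
) -> float:
    """Carry a rate measured at ``ph_from`` to ``ph_to`` along the shared slope.

    ``k_to = k_from · exp(a · (ph_to − ph_from))`` — the same fold change for
    every duplex, per the shared-slope assumption.  ``rate_label`` must name
    an anion-forming rate; tautomer rates are pH-independent and refuse to be
    extrapolated.
    """
    if rate_label in ("gs_es1", "es1_gs", "k_gs_es1", "k_es1_gs"):
        raise ValidationError(
            f"{rate_label!r} is a tautomer rate; tautomer kinetics are pH-independent"
        )
    if k_from < 0:
        raise ValidationError("rate must be non-negative")
    _warn_range(ph_to)
    return k_from * math.exp(model.slope_a * (ph_to - ph_from))


def forward_rate_from_pka(
    k_backward: float, p_es1: float, pka_app: float, ph: float
) -> float:
    """Forward wobble→anion rate at a given pH from the pH-independent backward rate.

    Uses the pKa-derived anion population and
    ``k_GS→ES2 = k_ES2→GS · p_ES2 / (1 − p_ES2 − p_ES1)``.
    """
    if k_backward <= 0:
        raise ValidationError("backward rate must be positive")
    if not 0 <= p_es1 < 1:
        raise ValidationError("p_ES1 must lie in [0, 1)")
    p_es2 = extrapolate_anion_population(pka_app, ph)
    if p_es1 + p_es2 >= 1:
        raise DomainError("excited-state populations exceed the ground state")
    return k_backward * p_es2 / (1.0 - p_es2 - p_es1)
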