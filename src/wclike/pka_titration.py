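"""pKa determination from chemical-shift titrations and excited-state populations.

Two routes to a pKa:

1. **NMR titration of an isolated nucleotide.**  ¹³C/¹⁵N chemical shifts of
   the N3/C4 resonance tracked versus pH are combined into a normalized
   chemical-shift perturbation (a weighted Euclidean distance with the
   BMRB-derived weights α_13C = 0.341, α_15N = 0.154, shifts referenced to
   the lowest-pH point) and fitted to the rearranged Henderson–Hasselbalch
   form::

       Δδ_obs(pH) = Δδ_deprot + (Δδ_prot − Δδ_deprot) / (1 + 10^(pH − pKa))

   Fractional species populations follow from the fitted endpoints.

2. **Apparent pKa from excited-state populations.**  With the anionic state
   population p_anion measured at a known pH by relaxation dispersion,
   ``pKa_app = pH − log10(p_anion / (p_wobble + p_tautomer))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model
from numpy.typing import NDArray

from .exceptions import DataError, DomainError, ValidationError

__all__ = [
    "ALPHA_13C",
    "ALPHA_15N",
    "TitrationSeries",
    "PkaFit",
    "combined_csp",
    "henderson_hasselbalch",
    "fit_henderson_hasselbalch",
    "species_populations",
    "apparent_pka_from_populations",
]

#: Weight factors for the combined chemical-shift perturbation, estimated
#: from heteronuclear shift ranges in the BMRB database.
ALPHA_13C = 0.341
ALPHA_15N = 0.154


@dataclass
class TitrationSeries:
    """pH-indexed ¹³C/¹⁵N chemical shifts for one titratable site.

    Shifts are absolute (ppm); perturbations are computed relative to the
    reference point (default: the lowest pH, where the site is most
    protonated).
    """

    ph: NDArray[np.float64]
    shift_13c: NDArray[np.float64]
    shift_15n: NDArray[np.float64]
    alpha_13c: float = ALPHA_13C
    alpha_15n: float = ALPHA_15N
    reference_ph: float | None = None

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.shift_13c = np.asarray(self.shift_13c, dtype=float)
        self.shift_15n = np.asarray(self.shift_15n, dtype=float)
        if not (self.ph.shape == self.shift_13c.shape == self.shift_15n.shape):
            raise ValidationError("pH and shift arrays must have equal length")
        if self.alpha_13c <= 0 or self.alpha_15n <= 0:
            raise ValidationError("CSP weights must be positive")
        order = np.argsort(self.ph)
        self.ph = self.ph[order]
        self.shift_13c = self.shift_13c[order]
        self.shift_15n = self.shift_15n[order]
        if np.any(np.diff(self.ph) <= 0):
            raise ValidationError("pH values must be distinct")

    @property
    def reference_index(self) -> int:
        if self.reference_ph is None:
            return 0
        idx = int(np.argmin(np.abs(self.ph - self.reference_ph)))
        return idx


def combined_csp(series: TitrationSeries) -> NDArray[np.float64]:
    """Normalized chemical-shift perturbation Δδ_obs at each pH.

    ``Δδ_obs = sqrt((α_13C·Δδ_13C)² + (α_15N·Δδ_15N)²)`` with shifts taken
    relative to the series' reference point (Δδ = 0 there by construction).
    """
    if np.any(~np.isfinite(series.shift_13c)) or np.any(~np.isfinite(series.shift_15n)):
        raise DataError("missing or non-finite chemical shift in titration series")
    i0 = series.reference_index
    dd13 = series.shift_13c - series.shift_13c[i0]
    dd15 = series.shift_15n - series.shift_15n[i0]
    return np.sqrt((series.alpha_13c * dd13) ** 2 + (series.alpha_15n * dd15) ** 2)


@dataclass
class PkaFit:
    """Henderson–Hasselbalch fit of a combined-CSP titration curve."""

    pka: float
    pka_sd: float
    dd_protonated: float
    dd_deprotonated: float
    dd_protonated_sd: float
    dd_deprotonated_sd: float
    residuals: NDArray[np.float64]
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.dd_protonated == self.dd_deprotonated:
            raise ValidationError("fit undefined: equal endpoint shifts")


def henderson_hasselbalch(
    ph: NDArray[np.float64] | float, pka: float, dd_prot: float, dd_deprot: float
):
    """Rearranged Henderson–Hasselbalch curve for the observed perturbation."""
    return dd_deprot + (dd_prot - dd_deprot) / (1.0 + 10.0 ** (np.asarray(ph) - pka))


def fit_henderson_hasselbalch(
    ph: NDArray[np.float64], dd_obs: NDArray[np.float64]
) -> PkaFit:
    """Nonlinear least-squares fit of (pKa, Δδ_prot, Δδ_deprot).

    Parameter sds are the square roots of the diagonal of the fit covariance
    matrix.  The fit is flagged non-identifiable (with a warning) when the
    transition midpoint falls outside the sampled pH range or its sd is
    large — e.g. for a grid that never crosses the transition.
    """
    ph = np.asarray(ph, dtype=float)
    dd_obs = np.asarray(dd_obs, dtype=float)
    if ph.size < 4:
        raise DataError("need >= 4 pH points for a Henderson-Hasselbalch fit")
    if ph.max() - ph.min() < 1.0:
        warnings.warn("pH grid spans < 1 unit; pKa may be poorly determined")
    model = Model(henderson_hasselbalch, independent_vars=["ph"])
    pars = model.make_params(
        pka=float(np.median(ph)),
        dd_prot=float(dd_obs[np.argmin(ph)]),
        dd_deprot=float(dd_obs[np.argmax(ph)]),
    )
    out = model.fit(dd_obs, pars, ph=ph)
    pka = float(out.params["pka"].value)
    pka_sd = out.params["pka"].stderr
    identifiable = True
    if pka_sd is None or not math.isfinite(pka_sd):
        pka_sd = float("nan")
        identifiable = False
    elif pka_sd > 0.5:
        identifiable = False
    if not (ph.min() - 0.5 <= pka <= ph.max() + 0.5):
        identifiable = False
    if not identifiable:
        warnings.warn(
            f"titration transition not identifiable on this pH grid (pKa={pka:.2f})"
        )

    def _sd(name: str) -> float:
        v = out.params[name].stderr
        return float(v) if v is not None and math.isfinite(v) else float("nan")

    return PkaFit(
        pka=pka,
        pka_sd=float(pka_sd),
        dd_protonated=float(out.params["dd_prot"].value),
        dd_deprotonated=float(out.params["dd_deprot"].value),
        dd_protonated_sd=_sd("dd_prot"),
        dd_deprotonated_sd=_sd("dd_deprot"),
        residuals=np.asarray(out.residual, dtype=float),
        identifiable=identifiable,
    )


def species_populations(csp_value: float, fit: PkaFit) -> tuple[float, float]:
    """(p_deprotonated, p_protonated) implied by an observed perturbation.

    ``p_deprot = (Δδ_prot − Δδ_obs)/(Δδ_prot − Δδ_deprot)``; values nudged
    outside [0, 1] by noise are clamped with a warning.
    """
    denom = fit.dd_protonated - fit.dd_deprotonated
    if denom == 0:
        raise DomainError("equal endpoint shifts: populations undefined")
    p_deprot = (fit.dd_protonated - csp_value) / denom
    if p_deprot < 0.0 or p_deprot > 1.0:
        warnings.warn(f"population {p_deprot:.3g} outside [0, 1]; clamping")
        p_deprot = min(max(p_deprot, 0.0), 1.0)
    return p_deprot, 1.0 - p_deprot


def apparent_pka_from_populations(
    ph: float,
    p_anion: float,
    p_wobble: float,
    p_tautomer: float,
    sds: tuple[float, float, float] | None = None,
):
    """Apparent pKa from excited-state populations at a known pH.

    ``pKa_app = pH − log10(p_anion / (p_wobble + p_tautomer))``.  When
    ``sds = (sd_anion, sd_wobble, sd_tautomer)`` is given, the first-order
    propagated sd is returned alongside the value.
    """
    for name, p in (("p_anion", p_anion), ("p_wobble", p_wobble), ("p_tautomer", p_tautomer)):
        if p < 0:
            raise ValidationError(f"{name} must be non-negative")
    if p_anion == 0:
        raise DomainError("p_anion = 0: apparent pKa is infinite")
    if p_anion + p_wobble + p_tautomer > 1 + 1e-9:
        raise ValidationError("populations exceed 1")
    neutral = p_wobble + p_tautomer
    if neutral <= 0:
        raise DomainError("no neutral population: apparent pKa undefined")
    value = ph - math.log10(p_anion / neutral)
    if sds is None:
        return value
    sd_a, sd_w, sd_t = sds
    ln10 = math.log(10.0)
    var = (sd_a / (ln10 * p_anion)) ** 2 + (sd_w**2 + sd_t**2) / (ln10 * neutral) ** 2
    return value, math.sqrt(var)
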