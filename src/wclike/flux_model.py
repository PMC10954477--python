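"""Equilibrium kinetic-flux model for G·T/U misincorporation pathways.

A misincorporation event passes from the wobble ground state (GS) through a
Watson–Crick-like excited state — tautomeric (ES1) or anionic (ES2) — before
the downstream step (rate k₂, e.g. the polymerase closing transition) commits
it to the misincorporated state (MIS).  The 4-species scheme::

    GS ⇌ ES1,  GS ⇌ ES2,  ES1 ⇌ ES2  (NMR-derived exchange rates)
    ES1 → MIS and ES2 → MIS at k₂;  MIS → ES1/ES2 at k₋₂

is integrated to equilibrium (t_sim = 10 s ≫ t_eq ≈ 5 ms), and the flux
through each route is composed from the equilibrium one-step fluxes
``F = p·k`` by the serial (harmonic sum) and parallel (plain sum) rules:

    F_tt = (1/(p_GS·k_GS→ES1) + 1/(p_ES1·k₂))⁻¹               tautomer direct
    F_ta = (1/(p_GS·k_GS→ES2) + 1/(p_ES2·k_ES2→ES1) + 1/(p_ES1·k₂))⁻¹
    F_aa = (1/(p_GS·k_GS→ES2) + 1/(p_ES2·k₂))⁻¹               anion direct
    F_at = (1/(p_GS·k_GS→ES1) + 1/(p_ES1·k_ES1→ES2) + 1/(p_ES2·k₂))⁻¹

    F_T = F_tt + F_ta,  F_A = F_aa + F_at,
    f_A = 100%·F_A/(F_T + F_A),  f_T = 100%·F_T/(F_T + F_A).

f_A interpolates between the thermodynamic limit p_ES2/(p_ES1+p_ES2)
(k₂ slow) and the kinetic limit k_GS→ES2/(k_GS→ES1+k_GS→ES2) (k₂ fast,
no minor exchange).  A 5-species variant prepends the NTP binding step
(G ⇌ GS at k_on/k_off); it barely moves f_A, which is why the 4-species
scheme is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.integrate import solve_ivp

from .exceptions import DomainError, ValidationError

__all__ = [
    "RATE_KEYS",
    "KineticScheme",
    "FullKineticScheme",
    "FluxResult",
    "solve_to_equilibrium",
    "pathway_fluxes",
    "relative_flux",
    "k2_sweep",
    "build_full_scheme_with_binding",
    "first_passage_route_fractions",
]

#: Exchange-rate keys of the 4-species scheme, in ``src_dst`` form.
RATE_KEYS = ("gs_es1", "es1_gs", "gs_es2", "es2_gs", "es1_es2", "es2_es1")


def _db_rates(p_es1, kex1, p_es2, kex2, kex_minor) -> dict[str, float]:
    """Forward/backward rates from (population, k_ex) pairs via detailed balance.

    On each edge ``k_i→j = k_ex,ij · p_j/(p_i + p_j)``, which reduces to
    ``k_f = p_ES·k_ex`` in the 2-state limit.
    """
    p_gs = 1.0 - p_es1 - p_es2
    if p_gs <= 0:
        raise ValidationError("excited-state populations exceed 1")
    rates = {
        "gs_es1": kex1 * p_es1 / (p_gs + p_es1) if kex1 else 0.0,
        "es1_gs": kex1 * p_gs / (p_gs + p_es1) if kex1 else 0.0,
        "gs_es2": kex2 * p_es2 / (p_gs + p_es2) if kex2 else 0.0,
        "es2_gs": kex2 * p_gs / (p_gs + p_es2) if kex2 else 0.0,
    }
    if kex_minor and (p_es1 + p_es2) > 0:
        rates["es1_es2"] = kex_minor * p_es2 / (p_es1 + p_es2)
        rates["es2_es1"] = kex_minor * p_es1 / (p_es1 + p_es2)
    else:
        rates["es1_es2"] = rates["es2_es1"] = 0.0
    return rates


@dataclass(frozen=True)
class KineticScheme:
    """4-species misincorporation scheme (GS, ES1, ES2, MIS).

    ``rates`` holds the six exchange rates keyed by :data:`RATE_KEYS`; ``k2``
    acts identically on ES1 and ES2, ``k_minus2`` on the reverse steps.
    Initial populations default to everything in the wobble ground state.
    """

    rates: Mapping[str, float]
    k2: float = 0.0
    k_minus2: float = 0.0
    t_sim: float = 10.0
    p0: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        rates = {k: float(dict(self.rates).get(k, 0.0)) for k in RATE_KEYS}
        if any(v < 0 for v in rates.values()) or self.k2 < 0 or self.k_minus2 < 0:
            raise ValidationError("all rates must be non-negative")
        if abs(sum(self.p0) - 1.0) > 1e-9 or any(p < 0 for p in self.p0):
            raise ValidationError("initial populations must be a distribution")
        object.__setattr__(self, "rates", rates)

    @classmethod
    def from_populations(
        cls,
        p_es1: float,
        kex_gs_es1: float,
        p_es2: float = 0.0,
        kex_gs_es2: float = 0.0,
        kex_minor: float = 0.0,
        k2: float = 0.0,
        k_minus2: float | None = None,
        **kwargs,
    ) -> "KineticScheme":
        """Build a scheme from fitted (population, k_ex) exchange parameters.

        ``k_minus2`` defaults to ``k2`` so the committed state never becomes
        absorbing during a sweep.
        """
        rates = _db_rates(p_es1, kex_gs_es1, p_es2, kex_gs_es2, kex_minor)
        return cls(rates=rates, k2=k2,
                   k_minus2=k2 if k_minus2 is None else k_minus2, **kwargs)

    def rate_matrix(self) -> NDArray[np.float64]:
        """Generator of d(p_GS, p_ES1, p_ES2, p_MIS)/dt (columns sum to 0)."""
        r = self.rates
        k2, km2 = self.k2, self.k_minus2
        A = np.array(
            [
                [-(r["gs_es1"] + r["gs_es2"]), r["es1_gs"], r["es2_gs"], 0.0],
                [r["gs_es1"], -(r["es1_gs"] + r["es1_es2"] + k2), r["es2_es1"], km2],
                [r["gs_es2"], r["es1_es2"], -(r["es2_gs"] + r["es2_es1"] + k2), km2],
                [0.0, k2, k2, -2.0 * km2],
            ]
        )
        return A

    @property
    def species(self) -> tuple[str, ...]:
        return ("GS", "ES1", "ES2", "MIS")


@dataclass(frozen=True)
class FullKineticScheme(KineticScheme):
    """5-species scheme with the NTP binding step G ⇌ GS prepended."""

    k_on: float = 0.0
    k_off: float = 0.0
    p0: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.k_on <= 0 or self.k_off < 0:
            raise ValidationError("binding rates must be positive")

    def rate_matrix(self) -> NDArray[np.float64]:
        r = self.rates
        k2, km2 = self.k2, self.k_minus2
        kon, koff = self.k_on, self.k_off
        return np.array(
            [
                [-kon, koff, 0.0, 0.0, 0.0],
                [kon, -(koff + r["gs_es1"] + r["gs_es2"]), r["es1_gs"], r["es2_gs"], 0.0],
                [0.0, r["gs_es1"], -(r["es1_gs"] + r["es1_es2"] + k2), r["es2_es1"], km2],
                [0.0, r["gs_es2"], r["es1_es2"], -(r["es2_gs"] + r["es2_es1"] + k2), km2],
                [0.0, 0.0, k2, k2, -2.0 * km2],
            ]
        )

    @property
    def species(self) -> tuple[str, ...]:
        return ("G", "GS", "ES1", "ES2", "MIS")


@dataclass
class FluxResult:
    """Equilibrium populations, pathway fluxes and the tautomer/anion split."""

    populations: dict[str, float]
    f_tt: float
    f_ta: float
    f_aa: float
    f_at: float
    flux_tautomer: float
    flux_anion: float
    f_a_percent: float
    f_t_percent: float
    k2: float
    k_minus2: float


def solve_to_equilibrium(
    scheme: KineticScheme, rtol: float = 1e-8, atol: float = 1e-12
) -> dict[str, float]:
    """Integrate the scheme to ``t_sim`` and return the species populations.

    Uses a stiff ODE solver with the (constant) generator as Jacobian and
    warns if the derivative norm at ``t_sim`` exceeds 1e-9 — i.e. the system
    has not actually equilibrated.
    """
    A = scheme.rate_matrix()
    p0 = np.asarray(scheme.p0, dtype=float)
    sol = solve_ivp(
        lambda t, p: A @ p,
        (0.0, scheme.t_sim),
        p0,
        method="BDF",
        jac=A,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise ValidationError(f"stiff solver failed for rates {scheme.rates}")
    p_eq = sol.y[:, -1]
    if np.linalg.norm(A @ p_eq) > 1e-9:
        warnings.warn(
            f"|dp/dt| = {np.linalg.norm(A @ p_eq):.2e} at t_sim={scheme.t_sim}s; "
            "system not fully equilibrated"
        )
    return dict(zip(scheme.species, p_eq))


def _serial(*step_fluxes: float) -> float:
    """Harmonic composition of sequential one-step fluxes; 0 if any step is 0."""
    if any(f <= 0.0 for f in step_fluxes):
        return 0.0
    return 1.0 / sum(1.0 / f for f in step_fluxes)


def pathway_fluxes(
    scheme: KineticScheme, eq_populations: Mapping[str, float]
) -> tuple[float, float, float, float]:
    """(F_tt, F_ta, F_aa, F_at) from equilibrium populations and rates."""
    r = scheme.rates
    p_gs = eq_populations["GS"]
    p1 = eq_populations["ES1"]
    p2 = eq_populations["ES2"]
    k2 = scheme.k2
    f1 = p_gs * r["gs_es1"]   # GS -> ES1
    f2 = p1 * k2              # ES1 -> MIS
    f3 = p_gs * r["gs_es2"]   # GS -> ES2
    f4 = p2 * k2              # ES2 -> MIS
    f5 = p2 * r["es2_es1"]    # ES2 -> ES1
    f6 = p1 * r["es1_es2"]    # ES1 -> ES2
    f_tt = _serial(f1, f2)
    f_ta = _serial(f3, f5, f2)
    f_aa = _serial(f3, f4)
    f_at = _serial(f1, f6, f4)
    return f_tt, f_ta, f_aa, f_at


def relative_flux(scheme: KineticScheme) -> FluxResult:
    """Solve to equilibrium and split the misincorporation flux by pathway."""
    pops = solve_to_equilibrium(scheme)
    f_tt, f_ta, f_aa, f_at = pathway_fluxes(scheme, pops)
    F_T = f_tt + f_ta
    F_A = f_aa + f_at
    total = F_T + F_A
    if total == 0:
        raise DomainError("no misincorporation flux (F_T + F_A = 0)")
    return FluxResult(
        populations=pops,
        f_tt=f_tt, f_ta=f_ta, f_aa=f_aa, f_at=f_at,
        flux_tautomer=F_T, flux_anion=F_A,
        f_a_percent=100.0 * F_A / total,
        f_t_percent=100.0 * F_T / total,
        k2=scheme.k2, k_minus2=scheme.k_minus2,
    )


def k2_sweep(
    scheme: KineticScheme,
    k2_grid: Sequence[float],
    track_k_minus2: bool = True,
) -> pd.DataFrame:
    """f_A(k₂) over a grid of downstream rates.

    By default ``k_minus2`` tracks ``k2`` (f_A, a ratio of fluxes homogeneous
    in the populations, is insensitive to this choice); pass
    ``track_k_minus2=False`` to hold the scheme's ``k_minus2`` fixed.
    """
    rows = []
    for k2 in k2_grid:
        if k2 <= 0:
            raise ValidationError("k2 grid must be positive")
        s = replace(scheme, k2=float(k2),
                    k_minus2=float(k2) if track_k_minus2 else scheme.k_minus2)
        res = relative_flux(s)
        rows.append(
            {"k2": float(k2), "f_a_percent": res.f_a_percent,
             "f_t_percent": res.f_t_percent,
             **{f"p_{k.lower()}": v for k, v in res.populations.items()}}
        )
    return pd.DataFrame(rows)


def build_full_scheme_with_binding(
    scheme: KineticScheme, k_on: float, k_off: float
) -> FullKineticScheme:
    """Extend a 4-species scheme with the G ⇌ GS binding step."""
    return FullKineticScheme(
        rates=scheme.rates, k2=scheme.k2, k_minus2=scheme.k_minus2,
        t_sim=scheme.t_sim, k_on=k_on, k_off=k_off,
    )


def thermodynamic_limit_fa(scheme: KineticScheme) -> float:
    """f_A as k₂ → 0: the equilibrium population split p_ES2/(p_ES1 + p_ES2)."""
    s0 = replace(scheme, k2=0.0, k_minus2=0.0)
    pops = solve_to_equilibrium(s0)
    p1, p2 = pops["ES1"], pops["ES2"]
    if p1 + p2 == 0:
        raise DomainError("no excited-state population")
    return 100.0 * p2 / (p1 + p2)


def kinetic_limit_fa(scheme: KineticScheme) -> float:
    """f_A as k₂ → ∞ with no minor exchange: the forward-rate split."""
    r = scheme.rates
    denom = r["gs_es1"] + r["gs_es2"]
    if denom == 0:
        raise DomainError("no forward rates")
    return 100.0 * r["gs_es2"] / denom


def first_passage_route_fractions(
    scheme: KineticScheme,
    n_events: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Stochastic oracle: fraction of first passages into MIS arriving from ES2/ES1.

    Simulates the embedded jump chain of the scheme for ``n_events``
    independent walkers started in GS, recording which excited state each
    walker occupied immediately before its first entry into MIS.  Returns
    ``(f_a_percent, f_t_percent)``.  Vectorized over walkers; intended as an
    independent cross-check of the serial/parallel flux algebra.
    """
    if scheme.k2 <= 0:
        raise ValidationError("first passage requires k2 > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = scheme.rates
    k2 = scheme.k2
    # states 0=GS, 1=ES1, 2=ES2; jump targets and probabilities per state
    out_rates = [
        np.array([r["gs_es1"], r["gs_es2"]]),                 # GS -> ES1, ES2
        np.array([r["es1_gs"], r["es1_es2"], k2]),            # ES1 -> GS, ES2, MIS
        np.array([r["es2_gs"], r["es2_es1"], k2]),            # ES2 -> GS, ES1, MIS
    ]
    targets = [np.array([1, 2]), np.array([0, 2, 3]), np.array([0, 1, 3])]
    cum = []
    for rates in out_rates:
        tot = rates.sum()
        if tot == 0:
            raise ValidationError("absorbing non-MIS state: no route to MIS")
        cum.append(np.cumsum(rates) / tot)
    state = np.zeros(n_events, dtype=np.int64)
    from_es2 = 0
    from_es1 = 0
    alive = np.arange(n_events)
    while alive.size:
        new_state = state[alive].copy()
        for s in (0, 1, 2):
            mask = state[alive] == s
            n = int(mask.sum())
            if n == 0:
                continue
            u = rng.random(n)
            choice = np.searchsorted(cum[s], u)
            new_state[mask] = targets[s][choice]
        absorbed = new_state == 3
        if absorbed.any():
            prev = state[alive][absorbed]
            from_es1 += int((prev == 1).sum())
            from_es2 += int((prev == 2).sum())
        state[alive] = new_state
        alive = alive[~absorbed]
    total = from_es1 + from_es2
    return 100.0 * from_es2 / total, 100.0 * from_es1 / total
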