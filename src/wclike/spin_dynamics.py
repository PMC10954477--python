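"""Bloch–McConnell forward model for off-resonance R1ρ relaxation dispersion.

Magnetization of a spin exchanging between *n* chemical states evolves under a
continuous spin lock according to a homogeneous 3n×3n generator that combines

* chemical exchange between states (first-order rates reconstructed from the
  equilibrium populations and the per-edge exchange rates ``k_ex = k_f + k_b``
  via detailed balance),
* per-state resonance offsets in the rotating frame,
* nutation about the x-axis at the spin-lock field ω₁, and
* transverse/longitudinal relaxation (R2 on x/y, R1 on z, decaying to zero —
  appropriate for spin-lock periods of ≲ 120 ms).

The observable is the projection of the propagated magnetization onto its
initial alignment axis; fitting the resulting decay to a mono-exponential
yields R1ρ for one (spin-lock power, carrier offset) condition.

Conventions
-----------
The ground state (GS) resonates at 0 by definition and an excited state (ES)
at +Δω, so in the rotating frame of the spin-lock carrier the offset of state
*s* is ``Ω_s = Ω_GS + Δω_s`` with ``Ω_GS = ω_obs − ω_RF`` the carrier offset
of the observed GS resonance.  A dispersion peak therefore appears at a
carrier offset of −Δω.  Δω in ppm converts to rad/s through the nucleus
Larmor frequency: ``Δω_rad = 2π · larmor_mhz · Δω_ppm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray

from .exceptions import (
    ConfigurationError,
    DataError,
    DomainError,
    PropagationError,
    ValidationError,
)

__all__ = [
    "DEFAULT_LARMOR_MHZ",
    "DEFAULT_ALIGNMENT_THRESHOLD",
    "ExchangeModel",
    "SpinLockCondition",
    "DecayCurve",
    "exchange_generator",
    "build_bm_matrix",
    "alignment_axis",
    "initial_magnetization",
    "simulate_decay",
    "simulate_r1rho",
    "r1rho_profile",
    "fit_monoexponential",
    "r2eff_transform",
    "fast_exchange_rex",
]

#: ¹⁵N Larmor frequency (MHz) on a 700 MHz (¹H) spectrometer.
DEFAULT_LARMOR_MHZ = 70.95

#: k_ex/|Δω| of the major ES above which the initial magnetization is aligned
#: along the population-average effective field instead of the GS field.
DEFAULT_ALIGNMENT_THRESHOLD = 5.0

_POP_TOL = 1e-12


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ExchangeModel:
    """n-state chemical exchange model with shared relaxation rates.

    Parameters
    ----------
    states
        Ordered state labels, ground state first.
    populations
        Equilibrium fraction of each state (same order); must sum to 1.
    kex
        Mapping of state pairs to exchange rates ``k_ex = k_f + k_b`` (1/s).
        Keys may be ``(a, b)`` tuples in either order or ``"a:b"`` strings.
        Absent edges have zero exchange.
    delta_omega
        ``{nucleus: {state: Δω in ppm}}`` chemical-shift offsets from the GS.
        The GS entry is implicitly 0 and must not be set to anything else.
    r1, r2
        Longitudinal and transverse relaxation rates (1/s), shared by all
        states.
    """

    states: tuple[str, ...]
    populations: tuple[float, ...]
    kex: Mapping[tuple[str, str], float] = field(default_factory=dict)
    delta_omega: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    r1: float = 2.0
    r2: float = 16.0

    def __post_init__(self) -> None:
        states = tuple(self.states)
        pops = tuple(float(p) for p in self.populations)
        if len(states) != len(pops) or not states:
            raise ValidationError("states and populations must align and be non-empty")
        if any(p < 0 for p in pops):
            raise ValidationError(f"negative population in {pops}")
        if abs(sum(pops) - 1.0) > 1e-9:
            raise ValidationError(f"populations must sum to 1, got {sum(pops)!r}")
        kex_norm: dict[tuple[str, str], float] = {}
        for key, value in dict(self.kex).items():
            if isinstance(key, str):
                a, b = key.split(":")
            else:
                a, b = key
            for lbl in (a, b):
                if lbl not in states:
                    raise ValidationError(f"unknown state {lbl!r} in kex edge {key!r}")
            if value < 0:
                raise ValidationError(f"negative exchange rate on edge {key!r}")
            kex_norm[_edge_key(a, b)] = float(value)
        dw_norm: dict[str, dict[str, float]] = {}
        gs = states[0]
        for nucleus, table in dict(self.delta_omega).items():
            table = dict(table)
            if abs(table.get(gs, 0.0)) > _POP_TOL:
                raise ValidationError(f"GS Δω must be 0 (nucleus {nucleus!r})")
            table[gs] = 0.0
            for lbl in table:
                if lbl not in states:
                    raise ValidationError(f"unknown state {lbl!r} in delta_omega")
            dw_norm[nucleus] = table
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "populations", pops)
        object.__setattr__(self, "kex", kex_norm)
        object.__setattr__(self, "delta_omega", dw_norm)

    # -- convenience accessors -------------------------------------------------
    @property
    def ground_state(self) -> str:
        return self.states[0]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def population(self, state: str) -> float:
        return self.populations[self.states.index(state)]

    def kex_between(self, a: str, b: str) -> float:
        return self.kex.get(_edge_key(a, b), 0.0)

    def rate(self, src: str, dst: str) -> float:
        """First-order rate ``k_src→dst`` from detailed balance.

        ``k_i→j = k_ex,ij · p_j / (p_i + p_j)`` so that
        ``p_i k_i→j = p_j k_j→i`` holds exactly on every edge.
        """
        kex = self.kex_between(src, dst)
        if kex == 0.0:
            return 0.0
        p_i, p_j = self.population(src), self.population(dst)
        if p_i + p_j == 0.0:
            return 0.0
        return kex * p_j / (p_i + p_j)

    def major_es(self) -> str | None:
        """The most populated excited state, or None for a 1-state model."""
        if self.n_states == 1:
            return None
        es = self.states[1:]
        return max(es, key=self.population)

    def dw_ppm(self, nucleus: str, state: str) -> float:
        if state == self.ground_state:
            return 0.0
        try:
            return self.delta_omega[nucleus][state]
        except KeyError as exc:
            raise ConfigurationError(
                f"no Δω entry for nucleus {nucleus!r}, state {state!r}"
            ) from exc


@dataclass(frozen=True)
class SpinLockCondition:
    """One spin-lock condition: power, carrier offset and relaxation delays.

    ``offset_hz`` is ``(ω_obs − ω_RF)/2π`` relative to the GS resonance of the
    observed nucleus.
    """

    power_hz: float
    offset_hz: float
    delays: tuple[float, ...] = (0.0, 0.04, 0.08, 0.12)
    larmor_mhz: float = DEFAULT_LARMOR_MHZ

    def __post_init__(self) -> None:
        if self.power_hz <= 0:
            raise ValidationError("spin-lock power must be positive")
        delays = tuple(float(t) for t in self.delays)
        if len(delays) < 2 or any(t < 0 for t in delays):
            raise ValidationError("need >= 2 non-negative relaxation delays")
        object.__setattr__(self, "delays", delays)

    @property
    def omega1(self) -> float:
        """Spin-lock field strength ω₁ (rad/s)."""
        return 2.0 * math.pi * self.power_hz

    @property
    def omega_gs(self) -> float:
        """Rotating-frame offset of the GS resonance (rad/s)."""
        return 2.0 * math.pi * self.offset_hz

    @property
    def theta(self) -> float:
        """Tilt of the GS effective field from the z-axis, in (0, π)."""
        return math.atan2(self.omega1, self.omega_gs)

    @property
    def omega_eff(self) -> float:
        """Magnitude of the GS effective field (rad/s)."""
        return math.hypot(self.omega1, self.omega_gs)


@dataclass
class DecayCurve:
    """Intensity vs relaxation delay for one spin-lock condition."""

    delays: NDArray[np.float64]
    intensities: NDArray[np.float64]
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValidationError("delays and intensities must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")


# ---------------------------------------------------------------------------
# Generator construction
# ---------------------------------------------------------------------------

def exchange_generator(model: ExchangeModel) -> NDArray[np.float64]:
    """n×n exchange generator L with ``L[i, j] = k_j→i`` and zero column sums."""
    n = model.n_states
    L = np.zeros((n, n))
    for i, si in enumerate(model.states):
        for j, sj in enumerate(model.states):
            if i == j:
                continue
            L[i, j] = model.rate(sj, si)
    L[np.diag_indices(n)] = -L.sum(axis=0)
    return L


def _state_offsets(model: ExchangeModel, cond: SpinLockCondition, nucleus: str) -> NDArray[np.float64]:
    """Rotating-frame offset Ω_s (rad/s) of every state for one nucleus."""
    ppm_to_rad = 2.0 * math.pi * cond.larmor_mhz
    return np.array(
        [cond.omega_gs + ppm_to_rad * model.dw_ppm(nucleus, s) for s in model.states]
    )


def build_bm_matrix(
    model: ExchangeModel, cond: SpinLockCondition, nucleus: str
) -> NDArray[np.float64]:
    """Full 3n×3n Bloch–McConnell generator for one nucleus and condition.

    Basis order is ``(Mx, My, Mz)`` per state, states in model order.  For a
    single state the spin block is::

        d/dt [Mx]   [-R2   -Ω    0 ] [Mx]
             [My] = [ Ω   -R2  -ω₁] [My]
             [Mz]   [ 0    ω₁  -R1] [Mz]

    and exchange couples corresponding components across states.
    """
    n = model.n_states
    omegas = _state_offsets(model, cond, nucleus)
    w1 = cond.omega1
    A = np.kron(exchange_generator(model), np.eye(3))
    for s in range(n):
        i = 3 * s
        blk = A[i : i + 3, i : i + 3]
        blk += np.array(
            [
                [-model.r2, -omegas[s], 0.0],
                [omegas[s], -model.r2, -w1],
                [0.0, w1, -model.r1],
            ]
        )
    return A


# ---------------------------------------------------------------------------
# Initial magnetization and propagation
# ---------------------------------------------------------------------------

def alignment_axis(
    model: ExchangeModel,
    cond: SpinLockCondition,
    nucleus: str,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
) -> NDArray[np.float64]:
    """Unit vector along which the equilibrated magnetization starts.

    Slow exchange (``k_ex/|Δω|`` of the major ES below the threshold) aligns
    along the GS effective field; fast exchange aligns along the
    population-average effective field.
    """
    major = model.major_es()
    use_average = False
    if major is not None:
        dw_rad = 2.0 * math.pi * cond.larmor_mhz * model.dw_ppm(nucleus, major)
        kex = model.kex_between(model.ground_state, major)
        if dw_rad == 0.0 or kex / abs(dw_rad) > alignment_threshold:
            use_average = True
    if use_average:
        omegas = _state_offsets(model, cond, nucleus)
        omega_z = float(np.dot(model.populations, omegas))
    else:
        omega_z = cond.omega_gs
    theta = math.atan2(cond.omega1, omega_z)
    return np.array([math.sin(theta), 0.0, math.cos(theta)])


def initial_magnetization(
    model: ExchangeModel,
    cond: SpinLockCondition,
    nucleus: str,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
) -> NDArray[np.float64]:
    """Length-3n start vector: population-weighted copies of the alignment axis."""
    axis = alignment_axis(model, cond, nucleus, alignment_threshold)
    return np.concatenate([p * axis for p in model.populations])


def _propagate_projection(
    A: NDArray[np.float64],
    m0: NDArray[np.float64],
    proj: NDArray[np.float64],
    delays: NDArray[np.float64],
) -> NDArray[np.float64]:
    """Projection of ``expm(A t) @ m0`` onto ``proj`` at each delay via eig."""
    w, V = np.linalg.eig(A)
    c = np.linalg.solve(V, m0.astype(complex))
    amps = (proj.astype(complex) @ V) * c
    out = np.real(np.exp(np.outer(delays, w)) @ amps)
    if not np.all(np.isfinite(out)):
        bad = delays[~np.isfinite(out)][0]
        raise PropagationError(f"magnetization overflow at delay {bad} s")
    return out


def simulate_decay(
    model: ExchangeModel,
    cond: SpinLockCondition,
    nucleus: str,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
) -> DecayCurve:
    """Simulate the spin-lock intensity decay for one condition.

    The intensity at each delay is the projection of the propagated
    magnetization onto the (replicated) initial alignment axis.
    """
    delays = np.asarray(cond.delays, dtype=float)
    A = build_bm_matrix(model, cond, nucleus)
    axis = alignment_axis(model, cond, nucleus, alignment_threshold)
    m0 = np.concatenate([p * axis for p in model.populations])
    proj = np.tile(axis, model.n_states)
    intensities = _propagate_projection(A, m0, proj, delays)
    return DecayCurve(delays=delays, intensities=intensities)


# ---------------------------------------------------------------------------
# Mono-exponential fitting
# ---------------------------------------------------------------------------

def _monoexp_fit_batch(
    t: NDArray[np.float64], I: NDArray[np.float64], n_iter: int = 10
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Unweighted least-squares fit of ``I0·exp(−R t)`` for batched curves.

    ``I`` has shape ``(..., len(t))``.  A log-linear fit (intensity-squared
    weighted, which linearizes the nonlinear problem) seeds Gauss–Newton
    refinement.  Returns ``(I0, R)`` with the leading batch shape.
    """
    I = np.asarray(I, dtype=float)
    t = np.asarray(t, dtype=float)
    w = np.clip(I, 1e-300, None) ** 2
    y = np.log(np.clip(I, 1e-300, None))
    sw = w.sum(axis=-1)
    st = (w * t).sum(axis=-1) / sw
    sy = (w * y).sum(axis=-1) / sw
    stt = (w * (t - st[..., None]) ** 2).sum(axis=-1)
    sty = (w * (t - st[..., None]) * (y - sy[..., None])).sum(axis=-1)
    slope = np.divide(sty, stt, out=np.zeros_like(sty), where=stt > 0)
    R = -slope
    I0 = np.exp(sy + slope * st)
    for _ in range(n_iter):
        E = np.exp(-R[..., None] * t)
        m = I0[..., None] * E
        r = I - m
        J1 = E
        J2 = -I0[..., None] * t * E
        a11 = (J1 * J1).sum(axis=-1)
        a12 = (J1 * J2).sum(axis=-1)
        a22 = (J2 * J2).sum(axis=-1)
        b1 = (J1 * r).sum(axis=-1)
        b2 = (J2 * r).sum(axis=-1)
        det = a11 * a22 - a12 * a12
        ok = np.abs(det) > 1e-300
        det = np.where(ok, det, 1.0)
        dI0 = np.where(ok, (a22 * b1 - a12 * b2) / det, 0.0)
        dR = np.where(ok, (a11 * b2 - a12 * b1) / det, 0.0)
        I0 = I0 + dI0
        R = R + dR
    return I0, R


def fit_monoexponential(
    curve: DecayCurve,
    mc_iterations: int = 500,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Fit ``I(t) = I0·exp(−R1ρ t)`` and return ``(R1ρ, sd)``.

    The uncertainty comes from Monte-Carlo resampling: synthetic curves are
    drawn around the best-fit decay with Gaussian noise of the curve's
    ``noise_sd`` and refitted; the sd of the refitted rates is reported.  When
    ``noise_sd`` is None it is estimated from the fit residuals.
    """
    t = curve.delays
    I = curve.intensities
    if np.unique(t).size < 2:
        raise DataError("need at least 2 distinct delays")
    if np.any(I <= 0):
        raise DataError("intensities must be positive for mono-exponential fitting")
    I0, R = _monoexp_fit_batch(t, I)
    I0 = float(I0)
    R = float(R)
    noise = curve.noise_sd
    if noise is None:
        resid = I - I0 * np.exp(-R * t)
        dof = max(t.size - 2, 1)
        noise = float(np.sqrt((resid**2).sum() / dof))
    if noise <= 0 or mc_iterations < 1:
        return R, 0.0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    best = I0 * np.exp(-R * t)
    samples = best + rng.normal(0.0, noise, size=(mc_iterations, t.size))
    samples = np.clip(samples, 1e-12, None)
    _, Rs = _monoexp_fit_batch(t, samples)
    return R, float(np.std(Rs, ddof=0))


def simulate_r1rho(
    model: ExchangeModel,
    cond: SpinLockCondition,
    nucleus: str,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
) -> float:
    """R1ρ for one condition: simulate the decay and fit a mono-exponential."""
    curve = simulate_decay(model, cond, nucleus, alignment_threshold)
    _, R = _monoexp_fit_batch(curve.delays, curve.intensities)
    return float(R)


def r1rho_profile(
    model: ExchangeModel,
    conds: Sequence[SpinLockCondition],
    nucleus: str,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
) -> NDArray[np.float64]:
    """Vectorized R1ρ over many spin-lock conditions (one nucleus).

    Conditions sharing an identical delay grid are propagated as a stacked
    eigendecomposition, which is what makes global fitting affordable.
    """
    conds = list(conds)
    out = np.empty(len(conds))
    groups: dict[tuple[float, ...], list[int]] = {}
    for i, c in enumerate(conds):
        groups.setdefault(c.delays, []).append(i)
    dim = 3 * model.n_states
    for delays, idx in groups.items():
        t = np.asarray(delays, dtype=float)
        N = len(idx)
        A = np.empty((N, dim, dim))
        M0 = np.empty((N, dim))
        proj = np.empty((N, dim))
        for k, i in enumerate(idx):
            c = conds[i]
            A[k] = build_bm_matrix(model, c, nucleus)
            axis = alignment_axis(model, c, nucleus, alignment_threshold)
            M0[k] = np.concatenate([p * axis for p in model.populations])
            proj[k] = np.tile(axis, model.n_states)
        w, V = np.linalg.eig(A)
        coef = np.linalg.solve(V, M0.astype(complex)[..., None])[..., 0]
        amps = np.einsum("nd,ndk->nk", proj.astype(complex), V) * coef
        # intensities: (N, n_delays)
        I = np.real(np.einsum("nk,ntk->nt", amps, np.exp(w[:, None, :] * t[None, :, None])))
        if not np.all(np.isfinite(I)):
            raise PropagationError("magnetization overflow in profile simulation")
        _, R = _monoexp_fit_batch(t, I)
        out[idx] = R
    return out


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def r2eff_transform(
    r1rho: float | NDArray[np.float64],
    r1: float,
    theta: float | NDArray[np.float64],
    r1rho_sd: float | NDArray[np.float64] | None = None,
):
    """Transform R1ρ to ``R2 + Rex = (R1ρ − R1·cos²θ)/sin²θ``.

    The sd, when supplied, is propagated through the same linear map.
    """
    sin2 = np.sin(theta) ** 2
    if np.any(np.asarray(sin2) == 0):
        raise DomainError("θ ∈ {0, π}: transform undefined on the z-axis")
    value = (r1rho - r1 * np.cos(theta) ** 2) / sin2
    if r1rho_sd is None:
        return value
    return value, r1rho_sd / sin2


def fast_exchange_rex(
    p_gs: float, p_es: float, delta_omega_rad: float, kex: float, omega_eff: float
) -> float:
    """Closed-form 2-state exchange contribution in the fast-exchange limit.

    ``Rex = p_GS·p_ES·Δω²·k_ex / (k_ex² + ω_eff²)`` — used as an analytic
    oracle for the numerical Bloch–McConnell machinery when k_ex ≫ |Δω|.
    """
    return p_gs * p_es * delta_omega_rad**2 * kex / (kex**2 + omega_eff**2)
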