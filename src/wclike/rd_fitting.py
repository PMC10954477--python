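"""Global fitting of R1ρ dispersion data to 2-/3-state exchange models.

The inverse problem: given observed R1ρ values over a grid of spin-lock
powers and carrier offsets for one or more nuclei, recover the exchange
parameters by weighted least squares against the Bloch–McConnell forward
model in :mod:`wclike.spin_dynamics`.  Thermodynamic and kinetic parameters
(populations, exchange rates) are shared across nuclei; chemical-shift
differences and relaxation rates are per nucleus.

Populations and exchange rates are fitted on a log10 scale (they span orders
of magnitude and must stay positive); Δω is fitted directly with a
non-negativity bound, which fixes the sign degeneracy of the dominant
dispersion.  Multi-start optimization over a coarse (k_ex, Δω-scale) grid
guards against local minima; ties in chi² are broken toward the smallest
k_ex for reproducibility.

Model comparison uses the residual-variance information criteria
``AIC = N·ln(chi²/N) + 2K`` and ``BIC = N·ln(chi²/N) + K·ln(N)`` with Akaike
weights ``w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)``; a Gaussian-likelihood variant
that uses the per-point uncertainties is available behind a switch.
Parameter uncertainties come from a Monte-Carlo scheme: resample each
observation around its fitted value with the observed sd, refit, and report
the spread.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ComparisonError, FitFailureError, ValidationError
from .spin_dynamics import (
    DEFAULT_ALIGNMENT_THRESHOLD,
    ExchangeModel,
    SpinLockCondition,
    r1rho_profile,
)

__all__ = [
    "RDRecord",
    "RDDataset",
    "FitResult",
    "fit_two_state",
    "fit_three_state_triangular",
    "monte_carlo_uncertainty",
    "model_selection",
    "assign_anion_state",
]

_LOG10 = np.log(10.0)


@dataclass(frozen=True)
class RDRecord:
    """One observed R1ρ value at one spin-lock condition."""

    nucleus: str
    cond: SpinLockCondition
    r1rho: float
    sd: float


@dataclass
class RDDataset:
    """Observed (or simulated) R1ρ values indexed by (nucleus, power, offset)."""

    records: list[RDRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.sd <= 0:
                raise ValidationError(
                    f"non-positive R1ρ sd for {rec.nucleus} at "
                    f"({rec.cond.power_hz} Hz, {rec.cond.offset_hz} Hz)"
                )

    @property
    def nuclei(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.nucleus, None)
        return list(seen)

    def subset(self, nucleus: str) -> list[RDRecord]:
        return [r for r in self.records if r.nucleus == nucleus]

    def check_fittable(self, nuclei: Sequence[str]) -> None:
        for nuc in nuclei:
            recs = self.subset(nuc)
            if len({r.cond.power_hz for r in recs}) < 2:
                raise ValidationError(
                    f"nucleus {nuc!r} needs >= 2 distinct spin-lock powers"
                )

    def data_hash(self) -> str:
        h = hashlib.sha1()
        for rec in sorted(
            self.records, key=lambda r: (r.nucleus, r.cond.power_hz, r.cond.offset_hz)
        ):
            h.update(
                f"{rec.nucleus}|{rec.cond.power_hz:.6g}|{rec.cond.offset_hz:.6g}|"
                f"{rec.r1rho:.9g}|{rec.sd:.9g};".encode()
            )
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus": [r.nucleus for r in self.records],
                "spinlock_hz": [r.cond.power_hz for r in self.records],
                "offset_hz": [r.cond.offset_hz for r in self.records],
                "r1rho": [r.r1rho for r in self.records],
                "r1rho_err": [r.sd for r in self.records],
            }
        )


@dataclass
class FitResult:
    """Outcome of a global dispersion fit.

    ``params`` holds linear-scale values: ``p_es``/``k_ex`` (2-state) or
    ``p_es1``/``p_es2``/``k_ex_gs_es1``/``k_ex_gs_es2``/``k_ex_es1_es2``
    (3-state), plus ``dw_<ES>_<nucleus>`` (ppm) and ``r1_<nucleus>`` /
    ``r2_<nucleus>`` (1/s).
    """

    model_type: str
    nuclei: list[str]
    params: dict[str, float]
    chi2: float
    n_obs: int
    n_params: int
    converged: bool
    n_starts: int
    param_sd: dict[str, float] | None = None
    aic: float | None = None
    bic: float | None = None
    akaike_weight: float | None = None
    bic_weight: float | None = None
    mc_warning: str | None = None
    metadata: dict = field(default_factory=dict)

    def to_exchange_model(self, nucleus: str, r1: float | None = None,
                          r2: float | None = None) -> ExchangeModel:
        """Materialize the fitted parameters as an ExchangeModel for one nucleus."""
        p = self.params
        r1 = p.get(f"r1_{nucleus}", r1)
        r2 = p.get(f"r2_{nucleus}", r2)
        if self.model_type == "2state":
            pes = p["p_es"]
            return ExchangeModel(
                states=("GS", "ES1"),
                populations=(1 - pes, pes),
                kex={("GS", "ES1"): p["k_ex"]},
                delta_omega={nucleus: {"ES1": p[f"dw_ES1_{nucleus}"]}},
                r1=r1, r2=r2,
            )
        p1, p2 = p["p_es1"], p["p_es2"]
        return ExchangeModel(
            states=("GS", "ES1", "ES2"),
            populations=(1 - p1 - p2, p1, p2),
            kex={
                ("GS", "ES1"): p["k_ex_gs_es1"],
                ("GS", "ES2"): p["k_ex_gs_es2"],
                ("ES1", "ES2"): p["k_ex_es1_es2"],
            },
            delta_omega={nucleus: {"ES1": p[f"dw_ES1_{nucleus}"],
                                   "ES2": p[f"dw_ES2_{nucleus}"]}},
            r1=r1, r2=r2,
        )


# ---------------------------------------------------------------------------
# Parameter vector <-> dict plumbing
# ---------------------------------------------------------------------------

class _ParamSpec:
    """Names, transforms and bounds of the free-parameter vector."""

    def __init__(self, model_type: str, nuclei: Sequence[str]):
        self.model_type = model_type
        self.nuclei = list(nuclei)
        names: list[tuple[str, str, tuple[float, float]]] = []
        if model_type == "2state":
            names.append(("p_es", "log10", (-6.0, -1.0)))
            names.append(("k_ex", "log10", (2.0, 6.0)))
            es_states = ["ES1"]
        elif model_type == "3state":
            names.append(("p_es1", "log10", (-6.0, -1.0)))
            names.append(("p_es2", "log10", (-6.0, -1.0)))
            names.append(("k_ex_gs_es1", "log10", (2.0, 6.0)))
            names.append(("k_ex_gs_es2", "log10", (2.0, 6.0)))
            names.append(("k_ex_es1_es2", "log10", (2.0, 6.0)))
            es_states = ["ES1", "ES2"]
        else:  # pragma: no cover
            raise ValueError(model_type)
        for es in es_states:
            for nuc in self.nuclei:
                names.append((f"dw_{es}_{nuc}", "lin", (0.0, 100.0)))
        for nuc in self.nuclei:
            names.append((f"r1_{nuc}", "lin", (0.05, 20.0)))
            names.append((f"r2_{nuc}", "lin", (0.5, 200.0)))
        self.entries = names

    @property
    def n(self) -> int:
        return len(self.entries)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([b[0] for _, _, b in self.entries])
        hi = np.array([b[1] for _, _, b in self.entries])
        return lo, hi

    def pack(self, params: dict[str, float]) -> np.ndarray:
        x = np.empty(self.n)
        for i, (name, tf, _) in enumerate(self.entries):
            v = params[name]
            x[i] = np.log10(v) if tf == "log10" else v
        return x

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, (name, tf, _) in enumerate(self.entries):
            out[name] = float(10.0 ** x[i]) if tf == "log10" else float(x[i])
        return out

    def sd_linear(self, x: np.ndarray, sd_x: np.ndarray) -> dict[str, float]:
        """Delta-method conversion of transformed-space sds to linear scale."""
        out: dict[str, float] = {}
        for i, (name, tf, _) in enumerate(self.entries):
            if tf == "log10":
                out[name] = float(_LOG10 * (10.0 ** x[i]) * sd_x[i])
            else:
                out[name] = float(sd_x[i])
        return out


def _build_model(spec: _ParamSpec, params: dict[str, float], nucleus: str) -> ExchangeModel:
    if spec.model_type == "2state":
        pes = params["p_es"]
        return ExchangeModel(
            states=("GS", "ES1"),
            populations=(1 - pes, pes),
            kex={("GS", "ES1"): params["k_ex"]},
            delta_omega={nucleus: {"ES1": params[f"dw_ES1_{nucleus}"]}},
            r1=params[f"r1_{nucleus}"], r2=params[f"r2_{nucleus}"],
        )
    p1, p2 = params["p_es1"], params["p_es2"]
    if p1 + p2 >= 1:
        raise ValidationError("excited-state populations exceed 1")
    return ExchangeModel(
        states=("GS", "ES1", "ES2"),
        populations=(1 - p1 - p2, p1, p2),
        kex={
            ("GS", "ES1"): params["k_ex_gs_es1"],
            ("GS", "ES2"): params["k_ex_gs_es2"],
            ("ES1", "ES2"): params["k_ex_es1_es2"],
        },
        delta_omega={nucleus: {"ES1": params[f"dw_ES1_{nucleus}"],
                               "ES2": params[f"dw_ES2_{nucleus}"]}},
        r1=params[f"r1_{nucleus}"], r2=params[f"r2_{nucleus}"],
    )


def _residual_fn(spec: _ParamSpec, grouped, alignment_threshold: float):
    def fun(x: np.ndarray) -> np.ndarray:
        params = spec.unpack(x)
        chunks = []
        for nuc, conds, obs, sds in grouped:
            model = _build_model(spec, params, nuc)
            sim = r1rho_profile(model, conds, nuc, alignment_threshold)
            chunks.append((obs - sim) / sds)
        return np.concatenate(chunks)

    return fun


def _group(data: RDDataset, nuclei: Sequence[str]):
    grouped = []
    for nuc in nuclei:
        recs = data.subset(nuc)
        conds = [r.cond for r in recs]
        obs = np.array([r.r1rho for r in recs])
        sds = np.array([r.sd for r in recs])
        grouped.append((nuc, conds, obs, sds))
    return grouped


def _dw_guess(data: RDDataset, nucleus: str) -> float:
    """Seed Δω from the carrier offset of the largest observed R2+Rex bump."""
    recs = data.subset(nucleus)
    best, best_val = 15.0, -np.inf
    for r in recs:
        th = r.cond.theta
        s2 = np.sin(th) ** 2
        if s2 < 1e-6:
            continue
        r2eff = (r.r1rho - 2.0 * np.cos(th) ** 2) / s2
        if r2eff > best_val and abs(r.cond.offset_hz) > 1e-9:
            best_val = r2eff
            best = abs(-r.cond.offset_hz / r.cond.larmor_mhz)
    return float(np.clip(best, 1.0, 95.0))


def _r2_guess(data: RDDataset, nucleus: str) -> float:
    """Median on/near-resonance high-power R2+Rex as an R2 seed."""
    recs = data.subset(nucleus)
    max_pw = max(r.cond.power_hz for r in recs)
    vals = []
    for r in recs:
        if r.cond.power_hz == max_pw and abs(r.cond.offset_hz) <= max_pw:
            th = r.cond.theta
            vals.append((r.r1rho - 2.0 * np.cos(th) ** 2) / np.sin(th) ** 2)
    return float(np.clip(np.median(vals) if vals else 16.0, 1.0, 150.0))


#: chi² margin inside which two optima are statistically indistinguishable;
#: ties are then broken toward the smallest total exchange rate.
TIE_CHI2 = 2.0


def _run_starts(
    data: RDDataset,
    spec: _ParamSpec,
    starts: list[dict[str, float]],
    alignment_threshold: float,
    max_nfev: int,
):
    grouped = _group(data, spec.nuclei)
    fun = _residual_fn(spec, grouped, alignment_threshold)
    lo, hi = spec.bounds()
    kex_idx = [i for i, (name, _, _) in enumerate(spec.entries)
               if name.startswith("k_ex")]
    fits = []
    for start in starts:
        x0 = np.clip(spec.pack(start), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                fun, x0, bounds=(lo, hi), method="trf", max_nfev=max_nfev,
                x_scale="jac", ftol=1e-9, xtol=1e-9, gtol=1e-9,
            )
        except (ValidationError, np.linalg.LinAlgError):
            continue
        fits.append(res)
    if not fits:
        raise FitFailureError(
            f"no optimizer start converged for {spec.model_type} fit "
            f"({len(starts)} starts attempted)"
        )
    # near-degenerate optima (Δchi² below the tie margin) are broken toward
    # the smallest summed exchange rate: reproducible, and avoids solutions
    # that trade tiny chi² gains for inflated minor-exchange rates
    best_chi2 = min(2 * r.cost for r in fits)
    tied = [r for r in fits if 2 * r.cost <= best_chi2 + TIE_CHI2]
    tied.sort(key=lambda r: float(np.sum(10.0 ** r.x[kex_idx])))
    return tied[0]


def _make_result(data, spec, res, n_starts) -> FitResult:
    x = res.x
    params = spec.unpack(x)
    chi2 = float(2 * res.cost)
    # covariance-based sd in transformed space (fast, refined later by MC)
    sd_cov: dict[str, float] | None = None
    try:
        J = res.jac
        JTJ = J.T @ J
        n_obs = res.fun.size
        dof = max(n_obs - spec.n, 1)
        cov = np.linalg.pinv(JTJ)
        sd_x = np.sqrt(np.clip(np.diag(cov), 0, None))
        sd_cov = spec.sd_linear(x, sd_x)
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    return FitResult(
        model_type=spec.model_type,
        nuclei=spec.nuclei,
        params=params,
        chi2=chi2,
        n_obs=res.fun.size,
        n_params=spec.n,
        converged=bool(res.status > 0),
        n_starts=n_starts,
        metadata={"data_hash": data.data_hash(), "covariance_sd": sd_cov,
                  "optimizer_status": int(res.status)},
    )


def fit_two_state(
    data: RDDataset,
    shared_nuclei: Sequence[str] | None = None,
    *,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
    kex_starts: Sequence[float] = (1e3, 5e3, 2e4),
    dw_scales: Sequence[float] = (1.0, 0.5),
    max_nfev: int = 400,
) -> FitResult:
    """Global 2-state fit sharing p_ES and k_ex across the listed nuclei.

    Free parameters: p_ES and k_ex (shared), Δω per nucleus, R1 and R2 per
    nucleus.  Multi-start over ``kex_starts`` × ``dw_scales`` applied to a
    data-driven Δω seed.
    """
    nuclei = list(shared_nuclei) if shared_nuclei else data.nuclei
    data.check_fittable(nuclei)
    spec = _ParamSpec("2state", nuclei)
    starts = []
    dw0 = {nuc: _dw_guess(data, nuc) for nuc in nuclei}
    r20 = {nuc: _r2_guess(data, nuc) for nuc in nuclei}
    for kex0, scale in itertools.product(kex_starts, dw_scales):
        start = {"p_es": 1e-3, "k_ex": kex0}
        for nuc in nuclei:
            start[f"dw_ES1_{nuc}"] = max(dw0[nuc] * scale, 1.0)
            start[f"r1_{nuc}"] = 2.0
            start[f"r2_{nuc}"] = r20[nuc]
        starts.append(start)
    res = _run_starts(data, spec, starts, alignment_threshold, max_nfev)
    return _make_result(data, spec, res, len(starts))


def fit_three_state_triangular(
    data: RDDataset,
    shared_nuclei: Sequence[str] | None = None,
    *,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
    init_from: FitResult | None = None,
    p2_starts: Sequence[float] = (5e-4, 3e-3),
    kex2_starts: Sequence[float] = (2e3, 8e3),
    dw2_levels: Sequence[float] = (5.0, 50.0),
    max_nfev: int = 400,
) -> FitResult:
    """Global 3-state triangular fit (GS ⇌ ES1 ⇌ ES2 ⇌ GS).

    Shares both populations and all three pairwise exchange rates across
    nuclei; Δω per nucleus per excited state and R1/R2 per nucleus are local.
    ES1 parameters are seeded from a 2-state fit (run internally when
    ``init_from`` is not supplied); the ES2 branch is multi-started over
    ``p2_starts × kex2_starts``.
    """
    nuclei = list(shared_nuclei) if shared_nuclei else data.nuclei
    data.check_fittable(nuclei)
    if init_from is None:
        init_from = fit_two_state(
            data, nuclei, alignment_threshold=alignment_threshold, max_nfev=max_nfev
        )
    spec = _ParamSpec("3state", nuclei)
    base = init_from.params

    def make_start(p2, kex2, dw2_by_nuc):
        start = {
            "p_es1": base.get("p_es", 1e-3),
            "p_es2": p2,
            "k_ex_gs_es1": base.get("k_ex", 5e3),
            "k_ex_gs_es2": kex2,
            "k_ex_es1_es2": 1e4,
        }
        for nuc in nuclei:
            start[f"dw_ES1_{nuc}"] = base.get(f"dw_ES1_{nuc}", 20.0)
            start[f"dw_ES2_{nuc}"] = dw2_by_nuc[nuc]
            start[f"r1_{nuc}"] = base.get(f"r1_{nuc}", 2.0)
            start[f"r2_{nuc}"] = base.get(f"r2_{nuc}", 16.0)
        return start

    starts = []
    hi = max(dw2_levels)
    for p2, kex2 in itertools.product(p2_starts, kex2_starts):
        starts.append(make_start(p2, kex2, {nuc: hi for nuc in nuclei}))
    # ES2 shift patterns: an ionized state may leave some nuclei unshifted,
    # so seed every on/off pattern of Δω_ES2 across the shared nuclei
    for pattern in itertools.product(dw2_levels, repeat=len(nuclei)):
        if all(v == hi for v in pattern):
            continue  # already covered above
        starts.append(make_start(1e-3, 5e3, dict(zip(nuclei, pattern))))
    res = _run_starts(data, spec, starts, alignment_threshold, max_nfev)
    return _make_result(data, spec, res, len(starts))


def monte_carlo_uncertainty(
    data: RDDataset,
    best: FitResult,
    n_iter: int = 200,
    seed: int | np.random.Generator | None = 0,
    *,
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD,
    max_nfev: int = 120,
) -> dict[str, float]:
    """Monte-Carlo parameter uncertainties for a converged fit.

    Each iteration resamples every observed R1ρ from
    ``Normal(fitted value, observed sd)`` and refits starting from the
    best-fit parameters (single start).  The per-parameter standard deviation
    across iterations is stored on ``best.param_sd`` and returned.
    """
    if not best.converged:
        raise FitFailureError("Monte-Carlo uncertainty requires a converged fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nuclei = best.nuclei
    spec = _ParamSpec(best.model_type, nuclei)
    grouped = _group(data, nuclei)
    # fitted values at the best parameters
    fitted: list[np.ndarray] = []
    for nuc, conds, obs, sds in grouped:
        model = _build_model(spec, best.params, nuc)
        fitted.append(r1rho_profile(model, conds, nuc, alignment_threshold))
    lo, hi = spec.bounds()
    x_best = np.clip(spec.pack(best.params), lo + 1e-9, hi - 1e-9)
    draws = []
    n_fail = 0
    for _ in range(n_iter):
        synth_records = []
        for (nuc, conds, obs, sds), sim in zip(grouped, fitted):
            vals = rng.normal(sim, sds)
            for cond, v, s in zip(conds, vals, sds):
                synth_records.append(RDRecord(nuc, cond, float(v), float(s)))
        synth = RDDataset(synth_records)
        fun = _residual_fn(spec, _group(synth, nuclei), alignment_threshold)
        try:
            res = least_squares(
                fun, x_best, bounds=(lo, hi), method="trf", max_nfev=max_nfev,
                x_scale="jac", ftol=1e-9, xtol=1e-9, gtol=1e-9,
            )
        except (ValidationError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        draws.append(res.x)
    warning = None
    if n_iter >= 1 and n_fail > 0.2 * n_iter:
        warning = f"{n_fail}/{n_iter} Monte-Carlo refits failed; uncertainties unreliable"
        warnings.warn(warning)
    if n_iter == 1:
        warning = "single Monte-Carlo iteration: degenerate sd = 0"
        warnings.warn(warning)
    X = np.array(draws)
    if X.size == 0:
        raise FitFailureError("all Monte-Carlo refits failed")
    sd_x = X.std(axis=0, ddof=0)
    # mean is irrelevant here; spread in transformed space -> linear scale
    sd = spec.sd_linear(x_best, sd_x)
    best.param_sd = sd
    best.mc_warning = warning
    return sd


def assign_anion_state(fit: FitResult, reporter: str | None = None) -> FitResult:
    """Resolve the ES1/ES2 labelling symmetry of a 3-state fit.

    A triangular 3-state model is invariant under exchanging the two excited
    states, so the optimizer may return them in either order.  Physically the
    anionic state barely shifts the guanine imino nitrogen (deprotonation
    happens on the pyrimidine N3) while the tautomeric state shifts both
    nuclei strongly; this relabels the fit so ES2 is the state with the
    smaller |Δω| on ``reporter`` (default: the first nucleus containing
    "G", else the first nucleus).  2-state fits pass through unchanged.
    """
    if fit.model_type != "3state":
        return fit
    if reporter is None:
        reporter = next((n for n in fit.nuclei if "G" in n.upper()), fit.nuclei[0])
    dw1 = abs(fit.params[f"dw_ES1_{reporter}"])
    dw2 = abs(fit.params[f"dw_ES2_{reporter}"])
    if dw2 <= dw1:
        return fit
    swap = {
        "p_es1": "p_es2", "p_es2": "p_es1",
        "k_ex_gs_es1": "k_ex_gs_es2", "k_ex_gs_es2": "k_ex_gs_es1",
    }
    for nuc in fit.nuclei:
        swap[f"dw_ES1_{nuc}"] = f"dw_ES2_{nuc}"
        swap[f"dw_ES2_{nuc}"] = f"dw_ES1_{nuc}"

    def remap(d: dict[str, float] | None) -> dict[str, float] | None:
        if d is None:
            return None
        return {k: d[swap.get(k, k)] for k in d}

    out = dataclasses.replace(fit, params=remap(fit.params),
                              param_sd=remap(fit.param_sd))
    cov = out.metadata.get("covariance_sd")
    if cov:
        out.metadata = dict(out.metadata, covariance_sd=remap(cov))
    return out


def model_selection(fits: Iterable[FitResult], *, use_likelihood: bool = False) -> list[FitResult]:
    """Rank fits of the same dataset by AIC; attach AIC/BIC and weights.

    Default criteria use the residual-variance form
    ``AIC = N ln(chi²/N) + 2K``; ``use_likelihood=True`` switches to the
    Gaussian log-likelihood with the known per-point sds, where
    ``AIC = chi² + 2K`` up to a shared additive constant.
    """
    fits = list(fits)
    hashes = {f.metadata.get("data_hash") for f in fits}
    if len(hashes) != 1 or None in hashes:
        raise ComparisonError("model selection requires fits of the identical dataset")
    n_set = {f.n_obs for f in fits}
    if len(n_set) != 1:
        raise ComparisonError("fits disagree on the number of observations")
    N = n_set.pop()
    for f in fits:
        K = f.n_params
        if use_likelihood:
            f.aic = f.chi2 + 2 * K
            f.bic = f.chi2 + K * np.log(N)
        else:
            f.aic = N * np.log(f.chi2 / N) + 2 * K
            f.bic = N * np.log(f.chi2 / N) + K * np.log(N)
    for attr, wattr in (("aic", "akaike_weight"), ("bic", "bic_weight")):
        vals = np.array([getattr(f, attr) for f in fits])
        delta = vals - vals.min()
        w = np.exp(-delta / 2)
        w /= w.sum()
        for f, wi in zip(fits, w):
            setattr(f, wattr, float(wi))
    return sorted(fits, key=lambda f: f.aic)
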