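"""Synthetic ground-truth fixtures: exchange models, noisy R1ρ data, titrations.

Every pipeline stage is testable without downloads: this module holds the
fitted exchange parameters of the four duplex contexts as ground-truth
models, simulates noisy spin-lock intensity decays over the experimental
acquisition grid (powers 400–2000 Hz, carrier offsets within ±3.5× the
power, 4 delays up to 120 ms), and generates noisy chemical-shift titration
curves over the measured pH grids.

The defaults reproduce the study conditions: 1.5% fractional Gaussian
intensity noise on the decay curves (typical for 1D selective-excitation
dispersion data) and 0.01-ppm shift noise on titrations.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .pka_titration import TitrationSeries
from .rd_fitting import RDDataset, RDRecord
from .spin_dynamics import (
    DEFAULT_ALIGNMENT_THRESHOLD,
    DEFAULT_LARMOR_MHZ,
    DecayCurve,
    ExchangeModel,
    SpinLockCondition,
    fit_monoexponential,
    simulate_decay,
)

__all__ = [
    "FixtureSpec",
    "RUTP_PH_GRID",
    "DTTP_PH_GRID",
    "make_exchange_fixture",
    "generate_rd_dataset",
    "generate_titration",
    "default_grid",
]

#: Measured sample pH values of the rUTP titration series.
RUTP_PH_GRID = (6.92, 7.41, 8.0, 8.13, 8.15, 8.22, 8.24, 8.27, 8.42, 8.78,
                8.87, 9.10, 9.20, 9.48, 9.93, 10.4, 11.2, 12.9, 13.5)

#: Measured sample pH values of the dTTP titration series.
DTTP_PH_GRID = (6.89, 7.40, 8.08, 8.39, 8.62, 9.65, 9.81, 10.3, 10.8, 11.1,
                11.5, 11.8, 12.0, 12.9, 13.6)

_DEFAULT_POWERS = (400.0, 800.0, 1200.0, 1600.0, 2000.0)
_DEFAULT_DELAYS = (0.0, 0.04, 0.08, 0.12)


def _norm_label(label: str) -> str:
    label = unicodedata.normalize("NFKC", label)
    for ch in ("·", ".", "-", "_", " "):
        label = label.replace(ch, "")
    return label.lower()


def _fixture_table() -> dict[tuple[str, float], ExchangeModel]:
    """Ground-truth exchange models per (duplex, pH).

    The two RNA:DNA hybrids carry the fitted central values (tautomeric ES1,
    anionic ES2; Δω in ppm, populations as fractions, k_ex in 1/s).  The
    dT·rG pH 7.8 anionic Δω values and the B-DNA dG·dT / A-RNA rG·rU entries
    are *synthetic stand-ins* (representative of prior duplex measurements,
    not fitted to any dataset here) so that every duplex label resolves.
    """
    t = {}
    # dT·rG hybrid, pH 7.4: 2-state tautomeric exchange
    p = 0.00083
    t[("dtrg", 7.4)] = ExchangeModel(
        states=("GS", "ES1"), populations=(1 - p, p),
        kex={("GS", "ES1"): 7200.0},
        delta_omega={"G-N1": {"ES1": 34.9}, "T-N3": {"ES1": 25.7}},
        r1=2.5, r2=18.0,
    )
    # dG·rU hybrid, pH 7.4: 3-state triangular (ES1 tautomer, ES2 anion)
    p1, p2 = 0.0019, 0.0012
    t[("dgru", 7.4)] = ExchangeModel(
        states=("GS", "ES1", "ES2"), populations=(1 - p1 - p2, p1, p2),
        kex={("GS", "ES1"): 4000.0, ("GS", "ES2"): 5000.0,
             ("ES1", "ES2"): 13000.0},
        delta_omega={"G-N1": {"ES1": 21.0, "ES2": 1.0},
                     "U-N3": {"ES1": 36.0, "ES2": 58.0}},
        r1=2.5, r2=18.0,
    )
    # dG·rU hybrid, pH 7.8: anion population ~0.3% (forward rate ~14 1/s)
    p1, p2 = 0.0019, 0.003
    t[("dgru", 7.8)] = ExchangeModel(
        states=("GS", "ES1", "ES2"), populations=(1 - p1 - p2, p1, p2),
        kex={("GS", "ES1"): 4000.0, ("GS", "ES2"): 4700.0,
             ("ES1", "ES2"): 13000.0},
        delta_omega={"G-N1": {"ES1": 21.0, "ES2": 1.0},
                     "U-N3": {"ES1": 36.0, "ES2": 58.0}},
        r1=2.5, r2=18.0,
    )
    # dT·rG hybrid, pH 7.8: anion ~0.02% (forward ~2 1/s); anionic Δω are
    # synthetic stand-ins mirroring the dG·rU anion shifts
    p1, p2 = 0.00083, 0.0002
    t[("dtrg", 7.8)] = ExchangeModel(
        states=("GS", "ES1", "ES2"), populations=(1 - p1 - p2, p1, p2),
        kex={("GS", "ES1"): 7200.0, ("GS", "ES2"): 10000.0,
             ("ES1", "ES2"): 13000.0},
        delta_omega={"G-N1": {"ES1": 34.9, "ES2": 1.0},
                     "T-N3": {"ES1": 25.7, "ES2": 58.0}},
        r1=2.5, r2=18.0,
    )
    # Synthetic stand-ins: B-DNA dG·dT and A-RNA rG·rU tautomeric exchange
    # (representative magnitudes for CGC-context duplexes; not fitted values)
    p = 0.0004
    t[("dgdt", 7.4)] = ExchangeModel(
        states=("GS", "ES1"), populations=(1 - p, p),
        kex={("GS", "ES1"): 6000.0},
        delta_omega={"G-N1": {"ES1": 36.0}, "T-N3": {"ES1": 27.0}},
        r1=2.5, r2=18.0,
    )
    p = 0.0011
    t[("rgru", 7.4)] = ExchangeModel(
        states=("GS", "ES1"), populations=(1 - p, p),
        kex={("GS", "ES1"): 3500.0},
        delta_omega={"G-N1": {"ES1": 22.0}, "U-N3": {"ES1": 35.0}},
        r1=2.5, r2=18.0,
    )
    return t


def make_exchange_fixture(label: str, ph: float = 7.4,
                          dw_scale: float = 1.0) -> ExchangeModel:
    """Ground-truth ExchangeModel for a duplex context at a given pH.

    ``dw_scale=0`` produces a no-dispersion control with every Δω zeroed.
    Raises a lookup error for unknown (label, pH) combinations.
    """
    table = _fixture_table()
    key = (_norm_label(label), float(ph))
    if key not in table:
        known = sorted({f"{k[0]}@{k[1]}" for k in table})
        raise KeyError(f"no fixture for {label!r} at pH {ph}; known: {known}")
    model = table[key]
    if dw_scale != 1.0:
        dw = {nuc: {st: v * dw_scale for st, v in tbl.items()}
              for nuc, tbl in model.delta_omega.items()}
        model = replace(model, delta_omega=dw)
    return model


def default_grid(
    powers: tuple[float, ...] = _DEFAULT_POWERS,
    n_offsets: int = 13,
    offset_span: float = 3.5,
    delays: tuple[float, ...] = _DEFAULT_DELAYS,
    larmor_mhz: float = DEFAULT_LARMOR_MHZ,
) -> list[SpinLockCondition]:
    """The acquisition grid: offsets evenly spaced in ±offset_span × power."""
    conds = []
    for pw in powers:
        for off in np.linspace(-offset_span * pw, offset_span * pw, n_offsets):
            conds.append(SpinLockCondition(pw, float(off), delays, larmor_mhz))
    return conds


@dataclass
class FixtureSpec:
    """Recipe for one synthetic R1ρ dataset."""

    label: str
    ph: float = 7.4
    model: ExchangeModel | None = None
    powers: tuple[float, ...] = _DEFAULT_POWERS
    n_offsets: int = 13
    offset_span: float = 3.5
    delays: tuple[float, ...] = _DEFAULT_DELAYS
    larmor_mhz: float = DEFAULT_LARMOR_MHZ
    noise_frac: float = 0.015
    seed: int = 0
    mc_iterations: int = 100
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD

    def __post_init__(self) -> None:
        if self.model is None:
            self.model = make_exchange_fixture(self.label, self.ph)
        if self.noise_frac < 0:
            raise ValidationError("noise fraction must be non-negative")
        if not all(400.0 <= p <= 2000.0 for p in self.powers):
            raise ValidationError("spin-lock powers outside the 400-2000 Hz grid")
        if self.offset_span > 3.5:
            raise ValidationError("offsets beyond ±3.5× the spin-lock power")
        if max(self.delays) > 0.120 or not 3 <= len(self.delays) <= 4:
            raise ValidationError("need 3-4 delays with maximum <= 120 ms")


def generate_rd_dataset(spec: FixtureSpec) -> tuple[RDDataset, dict]:
    """Simulate a noisy R1ρ dataset from a ground-truth model.

    For every nucleus and grid condition the spin-lock decay is simulated,
    Gaussian intensity noise of ``noise_frac`` (of the t=0 intensity) is
    added, and R1ρ ± sd is extracted by mono-exponential fitting with
    Monte-Carlo errors.  Returns the dataset and a truth record holding the
    generating model and settings; fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    conds = default_grid(spec.powers, spec.n_offsets, spec.offset_span,
                        spec.delays, spec.larmor_mhz)
    records = []
    for nucleus in sorted(model.delta_omega):
        for cond in conds:
            curve = simulate_decay(model, cond, nucleus, spec.alignment_threshold)
            noise_sd = spec.noise_frac * curve.intensities[0]
            noisy = curve.intensities + rng.normal(0.0, noise_sd, curve.intensities.shape) \
                if noise_sd > 0 else curve.intensities.copy()
            noisy = np.clip(noisy, 1e-9, None)
            obs = DecayCurve(curve.delays, noisy, noise_sd=noise_sd or None)
            r1rho, sd = fit_monoexponential(obs, spec.mc_iterations, rng)
            if sd <= 0:  # noiseless control datasets still need positive weights
                sd = 1e-6
            records.append(RDRecord(nucleus, cond, float(r1rho), float(sd)))
    dataset = RDDataset(
        records,
        metadata={"duplex": spec.label, "ph": spec.ph, "seed": spec.seed,
                  "noise_frac": spec.noise_frac},
    )
    truth = {
        "model": model,
        "label": spec.label,
        "ph": spec.ph,
        "seed": spec.seed,
        "noise_frac": spec.noise_frac,
    }
    return dataset, truth


def generate_titration(
    pka: float,
    endpoints: Mapping[str, tuple[float, float]],
    ph_grid,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator | None = 0,
) -> TitrationSeries:
    """Simulate a noisy two-nucleus titration series.

    ``endpoints`` maps ``"13C"``/``"15N"`` to (protonated, deprotonated)
    absolute shifts in ppm.  Each nucleus follows the Henderson–Hasselbalch
    transition with the common pKa; Gaussian noise of ``noise_sd`` ppm is
    added per nucleus per point before any perturbation combination.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ph = np.asarray(ph_grid, dtype=float)
    frac_deprot = 10.0 ** (ph - pka) / (1.0 + 10.0 ** (ph - pka))
    out = {}
    for nuc in ("13C", "15N"):
        prot, deprot = endpoints[nuc]
        clean = prot + (deprot - prot) * frac_deprot
        out[nuc] = clean + (rng.normal(0.0, noise_sd, ph.shape) if noise_sd > 0 else 0.0)
    return TitrationSeries(ph=ph, shift_13c=out["13C"], shift_15n=out["15N"])
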