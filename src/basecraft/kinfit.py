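"""Enzyme kinetics: Michaelis–Menten fits, single-protonation pH-rate
profiles, and fold-change bookkeeping across a mutational series."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "RateDataset",
    "MMFit",
    "PHProfileFit",
    "mm_rate",
    "fit_mm",
    "ph_profile",
    "fit_ph_profile",
    "fold_change",
    "mutant_series_table",
]


@dataclass
class RateDataset:
    """Initial-rate data: substrate (M), rate (M/s), total enzyme (M)."""

    substrate: np.ndarray
    rate: np.ndarray
    enzyme_total: float
    ph: float | None = None
    replicate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.substrate) != len(self.rate):
            raise ValueError("substrate and rate arrays differ in length")
        if (self.substrate <= 0).any():
            raise ValueError("substrate concentrations must be positive")


@dataclass
class MMFit:
    kcat: float  # 1/s
    km: float  # M
    se_kcat: float
    se_km: float
    low_substrate_warning: bool = False
    linear_regime: bool = False

    @property
    def kcat_over_km(self) -> float:
        return self.kcat / self.km


@dataclass
class PHProfileFit:
    max_eff: float  # M^-1 s^-1
    pka: float
    se_max: float
    se_pka: float
    unbracketed_warning: bool = False


def mm_rate(s, kcat: float, km: float, e0: float):
    """Michaelis–Menten initial rate v = kcat·E0·S/(Km + S), M/s."""
    s = np.asarray(s, dtype=float)
    v = kcat * e0 * s / (km + s)
    return v if v.ndim else float(v)


def fit_mm(data: RateDataset) -> MMFit:
    """Nonlinear least squares for (kcat, Km).

    kcat enters linearly given Km and is profiled out, leaving a 1-D search
    over log Km (global grid + bounded refinement, covering the quartile
    multistart).  Standard errors come from the Jacobian at the optimum.
    When the substrate grid never reaches 2 Km the kcat estimate is flagged
    as poorly constrained; when it stays below 0.2 Km the fit switches to
    the linear (kcat/Km) regime.
    """
    s, v, e0 = data.substrate, data.rate, data.enzyme_total
    levels = np.unique(s)
    if len(levels) < 4:
        raise ValueError("need at least 4 substrate levels")
    if levels.max() / levels.min() < 10:
        raise ValueError("substrate grid must span at least a 10-fold range")

    def kcat_given(km):
        x = e0 * s / (km + s)
        return float((x * v).sum() / (x * x).sum())

    def ssr_of(logkm):
        km = 10.0**logkm
        return float(((mm_rate(s, kcat_given(km), km, e0) - v) ** 2).sum())

    lo = math.log10(levels.min()) - 2
    hi = math.log10(levels.max()) + 2
    grid = np.linspace(lo, hi, 161)
    g0 = grid[int(np.argmin([ssr_of(g) for g in grid]))]
    res = minimize_scalar(ssr_of, bounds=(g0 - 0.5, g0 + 0.5), method="bounded")
    if not res.success:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {res.message}")
    km = float(10.0**res.x)
    kcat = kcat_given(km)

    # SEs from the analytic Jacobian of v(s; kcat, km)
    denom = km + s
    J = np.column_stack([e0 * s / denom, -kcat * e0 * s / denom**2])
    resid = mm_rate(s, kcat, km, e0) - v
    dof = max(len(s) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(J.T @ J)
    se_kcat, se_km = math.sqrt(max(cov[0, 0], 0)), math.sqrt(max(cov[1, 1], 0))

    # substrate far below Km: kcat and Km are individually unidentified but
    # their ratio is; flag rather than override (the profiled fit already
    # pins the ratio)
    linear = levels.max() < 0.2 * km
    warn = levels.max() < 2 * km
    return MMFit(kcat, km, se_kcat, se_km, low_substrate_warning=bool(warn), linear_regime=bool(linear))


def ph_profile(ph, max_eff: float, pka: float):
    """Single-protonation rising pH-rate profile:
    kcat/Km(pH) = (kcat/Km)max / (1 + 10^(pKa - pH))."""
    ph = np.asarray(ph, dtype=float)
    out = max_eff / (1.0 + 10.0 ** (pka - ph))
    return out if out.ndim else float(out)


def fit_ph_profile(ph, eff, weights=None, log_residuals: bool = True) -> PHProfileFit:
    """Fit ((kcat/Km)max, pKa) to a pH-rate profile.

    Residuals are taken on log10(kcat/Km) by default — efficiencies span
    orders of magnitude across the profile and per-pH errors are roughly
    proportional.  Multistart over pKa at the pH-grid quantiles.  A profile
    that does not bracket its midpoint is flagged (wide se_pka).
    """
    ph = np.asarray(ph, dtype=float)
    eff = np.asarray(eff, dtype=float)
    if len(ph) != len(eff):
        raise ValueError("ph and efficiency arrays differ in length")
    if len(np.unique(ph)) < 5:
        raise ValueError("need at least 5 pH points")
    if ph.max() - ph.min() < 2.0:
        raise ValueError("pH range must span at least 2 units")
    if (eff <= 0).any() and log_residuals:
        raise ValueError("non-positive efficiencies cannot be fitted on a log scale")
    w = np.ones_like(eff) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    def resid(params):
        lmax, pka = params
        model = ph_profile(ph, 10.0**lmax, pka)
        if log_residuals:
            return sw * (np.log10(model) - np.log10(eff))
        return sw * (model - eff)

    best = None
    for pka0 in np.quantile(ph, [0.15, 0.35, 0.5, 0.65, 0.85]):
        lmax0 = math.log10(max(eff.max(), 1e-300) * 1.05)
        try:
            sol = least_squares(resid, x0=[lmax0, pka0], method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("pH-profile fit did not converge from any start")
    lmax, pka = best.x
    max_eff = float(10.0**lmax)

    J = best.jac
    dof = max(len(ph) - 2, 1)
    sigma2 = 2.0 * best.cost / dof
    cov = sigma2 * np.linalg.pinv(J.T @ J)
    se_lmax = math.sqrt(max(cov[0, 0], 0))
    se_pka = math.sqrt(max(cov[1, 1], 0))
    se_max = max_eff * math.log(10.0) * se_lmax
    unbracketed = not (ph.min() <= pka <= ph.max())
    if unbracketed:
        se_pka = max(se_pka, 1.0)
    return PHProfileFit(max_eff, float(pka), se_max, se_pka, unbracketed_warning=bool(unbracketed))


def fold_change(numerator: float, denominator: float, decimals: int | None = 1) -> float:
    """Rounded ratio of two catalytic efficiencies (or rate constants)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    ratio = numerator / denominator
    return round(ratio, decimals) if decimals is not None else ratio


def mutant_series_table(entries, root: str | None = None) -> pd.DataFrame:
    """Fold-change bookkeeping across an ordered mutational series.

    ``entries``: iterable of (name, mutations, kcat_over_km, se).  The first
    entry is the root unless ``root`` names another.  fold_vs_parent uses
    the previous entry in the given order; relative SEs propagate in
    quadrature.
    """
    entries = list(entries)
    names = [e[0] for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate entry names")
    if root is None:
        root = names[0]
    if root not in names:
        raise ValueError(f"designated root {root!r} not among entries")
    root_val, root_se = next((e[2], e[3]) for e in entries if e[0] == root)
    rows = []
    prev_val, prev_se = None, None
    for name, muts, val, se in entries:
        rel = se / val if val else float("nan")
        if prev_val is None:
            fvp, fvp_se = 1.0, 0.0
        else:
            fvp = val / prev_val
            fvp_se = fvp * math.hypot(rel, prev_se / prev_val)
        fvr = val / root_val
        fvr_se = 0.0 if name == root else fvr * math.hypot(rel, root_se / root_val)
        rows.append(
            {
                "name": name,
                "mutations": ";".join(sorted(muts)) if muts else "",
                "kcat_over_km": val,
                "se": se,
                "fold_vs_parent": fvp,
                "fold_vs_parent_se": fvp_se,
                "fold_vs_root": fvr,
                "fold_vs_root_se": fvr_se,
            }
        )
        prev_val, prev_se = val, se
    return pd.DataFrame(rows)
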