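"""Fluorescence binding analysis.

The observed signal is modelled as linear in the free and bound ligand
concentrations, S = f_free (L - PL) + f_bound PL, with the complex
concentration PL given by the exact single-site quadratic (no "ligand in
excess" approximation, since protein is titrated into fixed fluorophore).
Titrations at several fixed ligand concentrations are fitted globally with
a shared dissociation constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TitrationDataset",
    "BindingFit",
    "bound_fraction",
    "global_fit_kd",
    "ligand_efficiency",
    "pka_shift_free_energy",
    "R_KCAL",
]

R_KCAL = 1.987e-3  # kcal/(mol K)


@dataclass
class TitrationDataset:
    """One titration: fixed total ligand, varying total protein, signal."""

    ligand_total: float  # M
    protein_totals: np.ndarray  # M
    signal: np.ndarray  # a.u.
    replicate_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.protein_totals = np.asarray(self.protein_totals, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
        if len(self.protein_totals) != len(self.signal):
            raise ValueError("protein and signal arrays differ in length")
        if (self.protein_totals < 0).any() or self.ligand_total < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class BindingFit:
    kd: float  # M
    f_free: np.ndarray  # per dataset (or length 1 when shared)
    f_bound: np.ndarray
    se_kd: float
    residual_norm: float
    non_saturable: bool
    shared_f: bool

    @property
    def enhancement(self) -> float:
        return float(np.mean(self.f_bound) / np.mean(self.f_free))


def bound_fraction(p_total, l_total, kd: float):
    """Complex concentration from the exact single-site quadratic,
    PL = ((P+L+Kd) - sqrt((P+L+Kd)^2 - 4 P L)) / 2, clamped to [0, min(P, L)]."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    P = np.asarray(p_total, dtype=float)
    L = np.asarray(l_total, dtype=float)
    if (P < 0).any() if P.ndim else P < 0:
        raise ValueError("negative protein concentration")
    b = P + L + kd
    disc = b * b - 4.0 * P * L
    neg = disc < 0
    if np.any(neg):
        warnings.warn("negative discriminant clamped to zero (roundoff)")
        disc = np.where(neg, 0.0, disc)
    pl = 0.5 * (b - np.sqrt(disc))
    pl = np.clip(pl, 0.0, np.minimum(P, L))
    return pl if pl.ndim else float(pl)


def _design_row(ds: TitrationDataset, kd: float):
    pl = bound_fraction(ds.protein_totals, ds.ligand_total, kd)
    free = ds.ligand_total - pl
    return free, pl


def _solve_coeffs(datasets, kd, weights, shared_f):
    """Linear WLS for (f_free, f_bound) given kd; returns coeffs and SSR."""
    if shared_f:
        rows, ys, ws = [], [], []
        for ds, w in zip(datasets, weights):
            free, pl = _design_row(ds, kd)
            rows.append(np.column_stack([free, pl]))
            ys.append(ds.signal)
            ws.append(w)
        A = np.vstack(rows)
        y = np.concatenate(ys)
        w = np.concatenate(ws)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        ssr = float((w * (A @ coef - y) ** 2).sum())
        return [coef] * len(datasets), ssr
    coeffs, ssr = [], 0.0
    for ds, w in zip(datasets, weights):
        free, pl = _design_row(ds, kd)
        A = np.column_stack([free, pl])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], ds.signal * sw, rcond=None)
        coeffs.append(coef)
        ssr += float((w * (A @ coef - ds.signal) ** 2).sum())
    return coeffs, ssr


def global_fit_kd(
    datasets,
    shared_f: bool = False,
    kd_bounds: tuple | None = None,
    non_saturable_occupancy: float = 0.3,
    relative_weights: bool = True,
) -> BindingFit:
    """Global weighted least-squares fit of the exact binding model with a
    shared dissociation constant.

    The fluorescence coefficients enter linearly and are profiled out, so
    the search is a robust 1-D optimization over log Kd (dense global scan
    + local refinement, which subsumes a multistart over log-spaced seeds).
    Weights are inverse replicate variance when provided; otherwise inverse
    squared signal by default (fluorescence error scales with the signal).
    Data that never reach 30% ligand occupancy at the optimum are flagged
    non-saturable.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    npts = sum(len(d.signal) for d in datasets)
    if npts < 5:
        raise ValueError("need at least 5 points in total")
    weights = []
    for ds in datasets:
        if ds.replicate_sd is not None and np.all(ds.replicate_sd > 0):
            weights.append(1.0 / ds.replicate_sd**2)
        elif relative_weights and np.all(ds.signal > 0):
            # fluorescence error is roughly proportional to the signal, so
            # equalize relative residuals
            weights.append(1.0 / ds.signal**2)
        else:
            weights.append(np.ones_like(ds.signal))
    med_p = float(np.median(np.concatenate([d.protein_totals for d in datasets])))
    if kd_bounds is None:
        kd_bounds = (med_p * 1e-3, med_p * 1e4)
    lo, hi = math.log10(kd_bounds[0]), math.log10(kd_bounds[1])

    def ssr_of(logkd):
        _, ssr = _solve_coeffs(datasets, 10.0**logkd, weights, shared_f)
        return ssr

    grid = np.linspace(lo, hi, 141)
    vals = np.array([ssr_of(g) for g in grid])
    if not np.all(np.isfinite(vals)):
        raise RuntimeError("binding fit failed: non-finite objective")
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(ssr_of, bounds=(max(lo, g0 - 0.5), min(hi, g0 + 0.5)), method="bounded")
    if not res.success:
        raise RuntimeError(f"binding fit did not converge: {res.message}")
    kd = float(10.0**res.x)
    coeffs, ssr = _solve_coeffs(datasets, kd, weights, shared_f)

    # SE of kd from the full-model Jacobian (numeric, via the profiled curvature)
    h = 1e-4
    f0, fp, fm = ssr_of(res.x), ssr_of(res.x + h), ssr_of(res.x - h)
    curv = (fp + fm - 2 * f0) / h**2  # d2SSR/dlogkd2
    nparam = 1 + (2 if shared_f else 2 * len(datasets))
    dof = max(npts - nparam, 1)
    sigma2 = ssr / dof
    if curv > 0:
        se_logkd = math.sqrt(2.0 * sigma2 / curv)
    else:
        se_logkd = float("inf")
    se_kd = kd * math.log(10.0) * se_logkd

    max_occ = max(
        float(np.max(bound_fraction(d.protein_totals, d.ligand_total, kd)) / d.ligand_total)
        if d.ligand_total > 0 else 0.0
        for d in datasets
    )
    # no binding signal: either the ligand never saturates, the fit is
    # degenerate (flat signal -> Kd unconstrained, SE spanning >10x), or the
    # model does not beat a constant signal (F-test)
    w_all = np.concatenate(weights)
    y_all = np.concatenate([d.signal for d in datasets])
    ybar = float((w_all * y_all).sum() / w_all.sum())
    ssr_const = float((w_all * (y_all - ybar) ** 2).sum())
    f_stat = max(ssr_const - ssr, 0.0) / max(nparam - 1, 1) / max(sigma2, 1e-300)
    non_saturable = (
        max_occ < non_saturable_occupancy or se_kd > 10.0 * kd or f_stat < 4.0
    )
    return BindingFit(
        kd=kd,
        f_free=np.array([c[0] for c in coeffs]),
        f_bound=np.array([c[1] for c in coeffs]),
        se_kd=float(se_kd),
        residual_norm=math.sqrt(ssr),
        non_saturable=non_saturable,
        shared_f=shared_f,
    )


def ligand_efficiency(kd: float, n_heavy: int, temperature: float = 298.15) -> float:
    """Free energy of binding (1 M standard state) per ligand heavy atom:
    LE = -RT ln(Kd / 1 M) / N_heavy, kcal/(mol · heavy atom)."""
    if kd <= 0 or n_heavy <= 0:
        raise ValueError("kd and heavy-atom count must be positive")
    return -R_KCAL * temperature * math.log(kd) / n_heavy


def pka_shift_free_energy(delta_pka: float, temperature: float = 298.15) -> float:
    """Free-energy cost of shifting a protonation constant:
    ΔΔG = ln(10) R T ΔpKa, kcal/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.log(10.0) * R_KCAL * temperature * delta_pka
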