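"""Chemical-shift-perturbation-guided position selection.

Amide CSPs between free and ligand-bound HSQC spectra rank residues whose
environment responds to binding; the most perturbed positions (optionally
excluding the first shell around the ligand) are chosen for saturation
mutagenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PeakPair", "CSPResult", "csp", "rank_csps", "select_perturbed_positions"]


@dataclass(frozen=True)
class PeakPair:
    residue: int
    dH_free: float
    dN_free: float
    dH_bound: float
    dN_bound: float


@dataclass
class CSPResult:
    residue: int
    csp: float  # ppm
    rank: int = 0
    selected: bool = False


def csp(pair: PeakPair, n_scale: float = 0.2) -> float:
    """Combined amide CSP: sqrt(ΔδH² + (n_scale·ΔδN)²), ppm.

    ``n_scale`` rescales the ¹⁵N dimension onto the ¹H scale (0.2, the
    common convention).
    """
    if n_scale <= 0:
        raise ValueError("n_scale must be positive")
    dh = pair.dH_bound - pair.dH_free
    dn = pair.dN_bound - pair.dN_free
    return math.hypot(dh, n_scale * dn)


def rank_csps(pairs, n_scale: float = 0.2) -> list[CSPResult]:
    """CSPs for a peak table, ranked descending (rank 1 = most perturbed)."""
    seen = set()
    for p in pairs:
        if p.residue in seen:
            raise ValueError(f"duplicate residue {p.residue} in peak table")
        seen.add(p.residue)
    results = [CSPResult(p.residue, csp(p, n_scale)) for p in pairs]
    for i, r in enumerate(sorted(results, key=lambda r: (-r.csp, r.residue)), start=1):
        r.rank = i
    return results


def select_perturbed_positions(
    results,
    mode: str = "top_k",
    k_or_tau=24,
    exclude: set | None = None,
):
    """Pick the strongly perturbed residues.

    ``top_k`` returns exactly k residues (boundary ties broken by residue
    number; a tie at the cut sets the returned flag); ``threshold`` returns
    all residues with CSP >= tau.  ``exclude`` drops residues (e.g. the
    ligand's first shell) before selection.  Returns (selected set,
    boundary_tie flag); also marks ``selected`` on the results.
    """
    results = list(results)
    if not results:
        raise ValueError("empty CSP table")
    if exclude:
        results = [r for r in results if r.residue not in exclude]
    tie = False
    if mode == "top_k":
        k = int(k_or_tau)
        if k > len(results):
            raise ValueError(f"k={k} exceeds table size {len(results)}")
        ordered = sorted(results, key=lambda r: (-r.csp, r.residue))
        cut = ordered[k - 1].csp if k else float("inf")
        if k < len(ordered) and math.isclose(ordered[k].csp, cut, rel_tol=0, abs_tol=1e-12):
            tie = True
        chosen = {r.residue for r in ordered[:k]}
    elif mode == "threshold":
        chosen = {r.residue for r in results if r.csp >= k_or_tau}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for r in results:
        r.selected = r.residue in chosen
    return chosen, tie
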