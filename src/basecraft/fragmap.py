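"""Fragment-screen analytics: conformer classification, site assignment,
hit-rate / occupancy bookkeeping and chemotype enrichment statistics.

The screen's readout is a table of fragments with hit flags, background
density correction (BDC) values and physicochemical properties; fragment
complexes are classified to binding sub-sites by contacts to the defining
aromatic-box residues combined with the gating tyrosine's rotamer state.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import comb
from scipy.stats import rankdata

from .structcore import ProteinStructure, chi_angles, fold_symmetric

__all__ = [
    "ConformerCall",
    "FragmentScreenRecord",
    "EnrichmentResult",
    "DEFAULT_TYR_CENTROIDS",
    "classify_tyr_conformer",
    "assign_fragment_site",
    "hit_rate",
    "occupancy_from_bdc",
    "heavy_atoms_from_formula",
    "enrichment_test",
    "adjust_bh",
]

#: Default (chi1, chi2) centroids for the two gating-tyrosine conformers.
#: Configuration data: calibrate against apo structures where both
#: conformers are modelled.  chi2 values are on the folded (-90, 90] scale.
DEFAULT_TYR_CENTROIDS = {"A": (-65.0, -85.0), "B": (-177.0, 80.0)}


@dataclass
class ConformerCall:
    residue: tuple
    chi1: float
    chi2: float
    label: str  # A | B | other
    distance_to_centroid: float  # circular degrees
    tie: bool = False


@dataclass
class FragmentScreenRecord:
    fragment_id: str
    dataset_quality_ok: bool
    is_hit: bool
    bdc: float | None = None
    occupancy: float | None = None
    site: str = "none"
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.is_hit and not self.dataset_quality_ok:
            raise ValueError("a hit requires a high-quality dataset")
        if self.occupancy is not None and not (0 <= self.occupancy <= 1):
            raise ValueError("occupancy outside [0, 1]")


@dataclass
class EnrichmentResult:
    property: str
    stat: float  # rank-sum of the hit group (midrank ties)
    effect: float  # median(hit) - median(library), property units
    p_perm: float
    p_adj: float | None = None
    exact: bool = False


def _circ_diff(a, b, period=360.0):
    d = (a - b) % period
    return min(d, period - d)


def classify_tyr_conformer(
    chi1: float,
    chi2: float,
    centroids: dict | None = None,
    max_radius: float = 40.0,
    residue: tuple = ("A", 0),
) -> ConformerCall:
    """Nearest-centroid call in wrapped (chi1, chi2) space.

    chi2 carries the ring's 2-fold symmetry, so it is folded to (-90, 90]
    (period 180°) before the circular Euclidean distance is computed; points
    farther than ``max_radius`` from both centroids are labelled "other".
    Exact ties go to A, with the tie flag set.
    """
    cents = centroids or DEFAULT_TYR_CENTROIDS
    c2 = fold_symmetric(chi2)
    dists = {}
    for lab, (m1, m2) in cents.items():
        d1 = _circ_diff(chi1, m1, 360.0)
        d2 = _circ_diff(c2, fold_symmetric(m2), 180.0)
        dists[lab] = math.hypot(d1, d2)
    order = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    best_lab, best_d = order[0]
    tie = len(order) > 1 and math.isclose(order[0][1], order[1][1], abs_tol=1e-9)
    if tie:
        best_lab = "A" if "A" in dists and math.isclose(dists["A"], best_d, abs_tol=1e-9) else best_lab
    label = best_lab if best_d <= max_radius else "other"
    return ConformerCall((residue[0], residue[1]), chi1, c2, label, best_d, tie)


def assign_fragment_site(
    complex_structure: ProteinStructure,
    fragment_resname: str,
    site_defs: dict,
    tyr_residue: tuple = ("A", 46),
    contact_cutoff: float = 4.5,
    centroids: dict | None = None,
    max_radius: float = 40.0,
    model: int = 0,
):
    """Assign a bound fragment to a sub-site.

    ``site_defs`` maps site label -> set of defining (chain, seqnum)
    residues.  The winner is the site whose defining residues make the most
    contacts (heavy-atom pairs within ``contact_cutoff``); the call is
    confirmed by the gating tyrosine's conformer (site A requires conformer
    A, site B conformer B), otherwise "other".  Returns
    (label, contact_table, ConformerCall).
    """
    frag_atoms = []
    for r in complex_structure.residues(model):
        if r.name == fragment_resname:
            frag_atoms.extend(a.pos for a in r.heavy_atoms())
    if not frag_atoms:
        raise ValueError(f"fragment residue {fragment_resname!r} not found")
    tree = cKDTree(np.array(frag_atoms))

    tyr = complex_structure.find(*tyr_residue, model)
    if tyr is None:
        raise ValueError(f"gating tyrosine {tyr_residue} not found")
    t_chis = chi_angles(tyr, canonicalize_symmetry=True)
    call = classify_tyr_conformer(
        t_chis[0], t_chis[1], centroids=centroids, max_radius=max_radius, residue=tyr_residue
    )

    contact_table = {}
    residues_hit = {}
    for site, resset in site_defs.items():
        per_res = {}
        for key in resset:
            r = complex_structure.find(key[0], key[1], model)
            if r is None:
                continue
            n = sum(1 for a in r.heavy_atoms() if len(tree.query_ball_point(a.pos, contact_cutoff)) > 0)
            per_res[tuple(key)] = n
        contact_table[site] = per_res
        residues_hit[site] = sum(1 for v in per_res.values() if v > 0)

    if not any(residues_hit.values()):
        return "other", contact_table, call
    ranked = sorted(residues_hit.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        winner = call.label if call.label in residues_hit else ranked[0][0]
    else:
        winner = ranked[0][0]
    label = winner if call.label == winner else "other"
    return label, contact_table, call


def hit_rate(n_hits: int, n_datasets: int) -> float:
    """Percent of processed datasets that yielded a fragment hit."""
    if n_datasets <= 0:
        raise ValueError("dataset count must be positive")
    if not (0 <= n_hits <= n_datasets):
        raise ValueError("hit count outside [0, n_datasets]")
    return 100.0 * n_hits / n_datasets


def occupancy_from_bdc(bdc: float) -> float:
    """Fragment occupancy from the background density correction: min(1, 2(1-BDC))."""
    if not (0.0 <= bdc <= 1.0):
        raise ValueError("BDC outside [0, 1]")
    return min(1.0, 2.0 * (1.0 - bdc))


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def heavy_atoms_from_formula(formula: str) -> int:
    """Heavy (non-hydrogen) atom count from a Hill-notation molecular formula."""
    consumed = 0
    total = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != consumed:
            raise ValueError(f"unparsable token at {formula[consumed:]!r}")
        consumed = m.end()
        el, count = m.group(1), int(m.group(2) or 1)
        if el not in ("H", "D", "T"):
            total += count
    if consumed != len(formula):
        raise ValueError(f"unparsable token at {formula[consumed:]!r}")
    return total


def enrichment_test(
    hit_values,
    library_values,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    property_name: str = "",
    exact_limit: int = 20_000,
) -> EnrichmentResult:
    """Rank-sum enrichment of a property in hits vs the library.

    The statistic is the midrank sum of the hit group over the pooled
    sample.  The p-value comes from label permutations: exhaustive
    enumeration when C(n, n_hit) <= ``exact_limit``, otherwise ``n_perm``
    seeded random subsets (with the add-one correction).
    """
    x = np.asarray(hit_values, dtype=float)
    y = np.asarray(library_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    n, n1 = len(pooled), len(x)
    obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    def tail_count(stats):
        stats = np.asarray(stats, dtype=float)
        if alternative == "greater":
            return (stats >= obs - 1e-12).sum()
        if alternative == "less":
            return (stats <= obs + 1e-12).sum()
        return (np.abs(stats - mu) >= abs(obs - mu) - 1e-12).sum()

    exact = comb(n, n1, exact=True) <= exact_limit
    if exact:
        stats = [ranks[list(idx)].sum() for idx in combinations(range(n), n1)]
        p = tail_count(stats) / len(stats)
    else:
        rng = np.random.default_rng(seed)
        u = rng.random((n_perm, n))
        idx = np.argpartition(u, n1 - 1, axis=1)[:, :n1]
        stats = ranks[idx].sum(axis=1)
        p = (tail_count(stats) + 1.0) / (n_perm + 1.0)
    effect = float(np.median(x) - np.median(y))
    return EnrichmentResult(property_name, obs, effect, float(min(p, 1.0)), exact=exact)


def adjust_bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini–Hochberg adjustment across a family of enrichment tests
    (fills ``p_adj`` in place and returns the list)."""
    m = len(results)
    order = np.argsort([r.p_perm for r in results])
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = m - rank_from_end
        val = min(prev, results[i].p_perm * m / k)
        adj[i] = val
        prev = val
    for r, a in zip(results, adj):
        r.p_adj = float(min(max(a, r.p_perm), 1.0))
    return results
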