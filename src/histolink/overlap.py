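"""Gene-list overlap tests and Level-1/2/3 list construction.

The central inference: do the genes that are differentially
histone-associated in a sire's sperm overlap the genes differentially
expressed in his offspring more than chance?  On a universe of N genes
the expected chance overlap of lists of sizes nA and nB is nA*nB/N; the
observed overlap is tested on the implied 2x2 membership table with
Pearson's chi-squared (1 df) and Yates' continuity correction.  An
overlap is significant only when p <= alpha *and* the observed count
exceeds the expectation (one-directional guard).

Phi sign convention: following the source convention, phi < 0 means the
observed overlap is *above* expectation (positive association) and
phi > 0 below it — the reverse of the textbook sign.  Pass
``phi_convention="textbook"`` for the usual orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "expected_overlap",
    "overlap_counts_test",
    "overlap_test",
    "OverlapResult",
    "GeneOverlap",
    "build_level_lists",
    "pairwise_concordance_grid",
    "set_composition",
    "compute_universe",
]

DEFAULT_ALPHA = 0.05


def expected_overlap(nA: int, nB: int, N: int) -> float:
    """Chance expectation nA*nB/N for the overlap of two lists drawn
    independently from a universe of N genes."""
    if N <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= nA <= N and 0 <= nB <= N):
        raise ValueError("list sizes must lie in [0, N]")
    return nA * nB / N


def _chi2_components(a, nA, nB, N):
    """Vectorized Pearson and Yates chi-squared for the 2x2 table implied
    by overlap a of lists sized nA, nB in universe N.  Degenerate margins
    give chi2 = 0."""
    a = np.asarray(a, dtype=float)
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    N = np.asarray(N, dtype=float)
    b = nA - a
    c = nB - a
    d = N - nA - nB + a
    denom = nA * (N - nA) * nB * (N - nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(denom > 0, N * (a * d - b * c) ** 2 / denom, 0.0)
        adj = np.maximum(np.abs(a * d - b * c) - N / 2.0, 0.0)
        yates = np.where(denom > 0, N * adj ** 2 / denom, 0.0)
    return pearson, yates, (b, c, d)


@dataclass
class OverlapResult:
    """2x2 overlap test result (statsmodels-style results object)."""

    nA: int
    nB: int
    N: int
    observed: int
    expected: float
    chi2_pearson: float
    p_pearson: float
    chi2_yates: float
    p_yates: float
    phi: float
    significant: bool
    p_fisher: float | None = None
    small_cells: bool = False
    label_a: str = "A"
    label_b: str = "B"

    @property
    def expected_rounded(self) -> int:
        """Display rounding, half away from zero (69.79 -> 70)."""
        return int(np.floor(self.expected + 0.5))

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "nA": self.nA, "nB": self.nB, "N": self.N,
            "observed": self.observed, "expected": self.expected,
            "chi2_pearson": self.chi2_pearson, "p_pearson": self.p_pearson,
            "chi2_yates": self.chi2_yates, "p_yates": self.p_yates,
            "phi": self.phi, "significant": bool(self.significant),
            "p_fisher": self.p_fisher, "small_cells": self.small_cells,
        }

    def summary(self) -> str:
        lines = [
            f"Overlap test: {self.label_a} (n={self.nA}) x "
            f"{self.label_b} (n={self.nB}) on N={self.N}",
            f"  observed {self.observed}  expected {self.expected:.2f} "
            f"(~{self.expected_rounded})",
            f"  Pearson chi2={self.chi2_pearson:.3f} p={self.p_pearson:.3g}",
            f"  Yates   chi2={self.chi2_yates:.3f} p={self.p_yates:.3g}",
            f"  phi={self.phi:+.4f}  significant={bool(self.significant)}",
        ]
        if self.small_cells and self.p_fisher is not None:
            lines.append(f"  small expected cell(s): Fisher exact "
                         f"p={self.p_fisher:.3g}")
        return "\n".join(lines)


def overlap_counts_test(observed: int, nA: int, nB: int, N: int,
                        alpha: float = DEFAULT_ALPHA,
                        phi_convention: str = "paper",
                        label_a: str = "A",
                        label_b: str = "B") -> OverlapResult:
    """Overlap test from counts alone (see module docstring).

    Significance requires p <= alpha under *both* corrections computed
    (i.e. the more conservative Yates p governs) and observed > expected.
    When any expected cell of the 2x2 table is below 5, a Fisher exact p
    is attached alongside with a warning flag.
    """
    exp = expected_overlap(nA, nB, N)
    lo, hi = max(0, nA + nB - N), min(nA, nB)
    if not lo <= observed <= hi:
        raise ValueError(
            f"observed={observed} incompatible with nA={nA}, nB={nB}, N={N}")
    pearson, yates, (b, c, d) = _chi2_components(observed, nA, nB, N)
    pearson, yates = float(pearson), float(yates)
    degenerate = nA in (0, N) or nB in (0, N)
    if degenerate:
        p_pearson = p_yates = 1.0
    else:
        p_pearson = float(stats.chi2.sf(pearson, df=1))
        p_yates = float(stats.chi2.sf(yates, df=1))
    mag = np.sqrt(pearson / N)
    sign = 1.0 if observed > exp else (-1.0 if observed < exp else 0.0)
    if phi_convention == "paper":
        phi = -sign * mag
    elif phi_convention == "textbook":
        phi = sign * mag
    else:
        raise ValueError(f"unknown phi convention {phi_convention!r}")
    # expected cell counts under independence
    ra, rb = nA, N - nA
    ca, cb = nB, N - nB
    exp_cells = np.array([ra * ca, ra * cb, rb * ca, rb * cb],
                         dtype=float) / N
    small = bool((exp_cells < 5).any()) and not degenerate
    p_fisher = None
    if small:
        warnings.warn("expected cell count < 5; Fisher exact p attached")
        _, p_fisher = stats.fisher_exact(
            [[observed, b], [c, d]], alternative="two-sided")
        p_fisher = float(p_fisher)
    p_verdict = max(p_pearson, p_yates)
    significant = (p_verdict <= alpha) and (observed > exp)
    return OverlapResult(nA=nA, nB=nB, N=N, observed=observed, expected=exp,
                         chi2_pearson=pearson, p_pearson=p_pearson,
                         chi2_yates=yates, p_yates=p_yates, phi=float(phi),
                         significant=significant, p_fisher=p_fisher,
                         small_cells=small, label_a=label_a, label_b=label_b)


def overlap_test(list_a, list_b, universe, alpha: float = DEFAULT_ALPHA,
                 phi_convention: str = "paper", label_a: str = "A",
                 label_b: str = "B") -> OverlapResult:
    """Overlap test of two gene lists on an explicit universe."""
    universe = set(universe)
    a, b = set(list_a), set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    return overlap_counts_test(len(a & b), len(a), len(b), len(universe),
                               alpha=alpha, phi_convention=phi_convention,
                               label_a=label_a, label_b=label_b)


class GeneOverlap:
    """Model-style wrapper: two gene lists plus a universe; ``fit()``
    returns the :class:`OverlapResult`."""

    def __init__(self, list_a, list_b, universe,
                 label_a: str = "A", label_b: str = "B"):
        self.list_a = set(list_a)
        self.list_b = set(list_b)
        self.universe = set(universe)
        self.label_a = label_a
        self.label_b = label_b

    def fit(self, alpha: float = DEFAULT_ALPHA,
            phi_convention: str = "paper") -> OverlapResult:
        return overlap_test(self.list_a, self.list_b, self.universe,
                            alpha=alpha, phi_convention=phi_convention,
                            label_a=self.label_a, label_b=self.label_b)


# ---------------------------------------------------------------------------
# list construction

def build_level_lists(de_calls: pd.DataFrame,
                      pedigree: dict[str, list[str]], level: int,
                      direction: str | None = None) -> dict[str, frozenset]:
    """Level-1/2/3 DE gene lists from per-embryo DE calls.

    Level 1: one deduplicated list per embryo.  Level 2 ("family"): the
    union of DE genes over a sire's embryos.  Level 3 ("genotype"): the
    union over all embryos of all sires in the pedigree.  ``de_calls``
    needs columns embryo_id, gene_id and (optionally filtered) direction;
    only rows with de == True are used if a ``de`` column is present.
    Every embryo must belong to exactly one sire.
    """
    calls = de_calls
    if "de" in calls.columns:
        calls = calls[calls["de"]]
    if direction is not None:
        calls = calls[calls["direction"] == direction]
    embryo_sire: dict[str, str] = {}
    for sire, embryos in pedigree.items():
        for e in embryos:
            if e in embryo_sire:
                raise ValueError(f"embryo {e!r} assigned to two sires")
            embryo_sire[e] = sire
    orphans = set(calls["embryo_id"]) - set(embryo_sire)
    if orphans:
        raise ValueError(f"embryos without a sire: {sorted(orphans)}")
    per_embryo = {e: frozenset(g["gene_id"])
                  for e, g in calls.groupby("embryo_id")}
    if level == 1:
        return {e: per_embryo.get(e, frozenset())
                for embryos in pedigree.values() for e in embryos}
    if level == 2:
        return {sire: frozenset().union(*(per_embryo.get(e, frozenset())
                                          for e in embryos))
                for sire, embryos in pedigree.items()}
    if level == 3:
        all_genes = frozenset().union(*per_embryo.values()) \
            if per_embryo else frozenset()
        return {"genotype": all_genes}
    raise ValueError("level must be 1, 2 or 3")


def pairwise_concordance_grid(histone_calls: dict[str, dict[str, set]],
                              de_lists: dict[str, set], universe,
                              alpha: float = DEFAULT_ALPHA,
                              phi_convention: str = "paper") -> pd.DataFrame:
    """Overlap-test grid: every (sire, MAT stratum) x DE list.

    ``histone_calls`` maps sire -> {"MAT+": set, "MAT-": set}; the
    combined "MAT-/+" stratum (deduplicated union) is added per sire.
    Returns a long frame with one row per grid cell carrying the full
    OverlapResult fields plus a shading field (``significant``).
    """
    universe = set(universe)
    rows = []
    for sire in sorted(histone_calls):
        strata = dict(histone_calls[sire])
        strata["MAT-/+"] = set(strata.get("MAT+", set())) | \
            set(strata.get("MAT-", set()))
        for stratum in ("MAT-", "MAT+", "MAT-/+"):
            genes = set(strata.get(stratum, set()))
            for de_label in sorted(de_lists):
                res = overlap_test(genes, de_lists[de_label], universe,
                                   alpha=alpha,
                                   phi_convention=phi_convention,
                                   label_a=f"{sire}:{stratum}",
                                   label_b=de_label)
                rec = res.to_dict()
                rec.update({"sire": sire, "stratum": stratum,
                            "de_list": de_label})
                rows.append(rec)
    cols = ["sire", "stratum", "de_list", "nA", "nB", "N", "observed",
            "expected", "chi2_pearson", "p_pearson", "chi2_yates",
            "p_yates", "phi", "significant", "p_fisher", "small_cells"]
    return pd.DataFrame(rows)[cols]


def set_composition(list_a, reference_sets: dict[str, set], universe,
                    alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Percent of ``list_a`` falling into each named reference set, with
    a Yates chi-squared against the universe baseline frequency."""
    universe = set(universe)
    a = set(list_a)
    if not a <= universe:
        raise ValueError("list must be a subset of the universe")
    rows = []
    for name in sorted(reference_sets):
        ref = set(reference_sets[name])
        if not ref <= universe:
            raise ValueError(f"reference set {name!r} not within universe")
        inter = len(a & ref)
        if len(a) == 0:
            rows.append({"reference": name, "n_list": 0, "n_ref": len(ref),
                         "overlap": 0, "percent": np.nan,
                         "baseline_percent": 100.0 * len(ref) / len(universe),
                         "chi2_yates": np.nan, "p_yates": np.nan,
                         "significant": False})
            continue
        res = overlap_counts_test(inter, len(a), len(ref), len(universe),
                                  alpha=alpha)
        rows.append({
            "reference": name, "n_list": len(a), "n_ref": len(ref),
            "overlap": inter, "percent": round(100.0 * inter / len(a), 1),
            "baseline_percent": 100.0 * len(ref) / len(universe),
            "chi2_yates": res.chi2_yates, "p_yates": res.p_yates,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)


def compute_universe(platform_gene_lists: list) -> set:
    """Universe = genes interrogated by *all* platforms (intersection)."""
    lists = [set(p) for p in platform_gene_lists]
    if not lists:
        raise ValueError("at least one platform gene list required")
    universe = set.intersection(*lists)
    if not universe:
        raise ValueError("platform lists share no genes")
    return universe
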