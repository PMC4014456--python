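"""Differential expression in individual 2-cell embryos.

Each experimental embryo (the product of a single sperm) is contrasted
against a pool of control embryos with a per-gene one-vs-group t
contrast using the pooled control variance — the only estimable contrast
with a single experimental sample.  P-values are Benjamini-Hochberg
adjusted within each embryo-vs-pool comparison; a gene is called DE at
p_adj below the FDR threshold (default 0.1).  The fold ratio is
2^(embryo - control mean) on the log2 scale, so direction is "up" for
ratio > 1 and "down" for ratio < 1.  Coefficients of variation
(Cv = sigma/mu, percent, linear scale) flag highly variable genes at
Cv > 5% — flagged, per the source protocol, but never excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "de_single_embryo",
    "compute_cv",
    "summarize_direction",
    "EmbryoDEModel",
    "DEResults",
]

DEFAULT_FDR = 0.1
DEFAULT_CV_THRESHOLD = 5.0  # percent


def de_single_embryo(matrix: pd.DataFrame, embryo_id: str,
                     control_ids: list[str], fdr: float = DEFAULT_FDR,
                     cv_threshold: float = DEFAULT_CV_THRESHOLD) -> pd.DataFrame:
    """Per-gene contrast of one embryo against the control pool.

    ``matrix`` is genes x samples on the log2 scale.  Returns a frame
    with gene_id, ratio (linear fold), p, p_adj (BH within this
    comparison), direction, de (p_adj < fdr) and cv_flag (control Cv
    above threshold).  Requires >= 3 controls (variance inestimable
    otherwise).
    """
    control_ids = list(control_ids)
    if len(control_ids) < 3:
        raise ValueError("need at least 3 control embryos to estimate "
                         "the control variance")
    if embryo_id in control_ids:
        raise ValueError("embryo cannot be part of its own control pool")
    x = matrix[embryo_id].to_numpy(dtype=float)
    ctl = matrix[control_ids].to_numpy(dtype=float)
    n = ctl.shape[1]
    mu = ctl.mean(axis=1)
    sd = ctl.std(axis=1, ddof=1)
    sd = np.maximum(sd, 1e-12)
    t = (x - mu) / (sd * np.sqrt(1.0 + 1.0 / n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p_adj = multipletests(p, method="fdr_bh")[1]
    ratio = np.power(2.0, x - mu)
    cv = compute_cv(matrix, control_ids)
    out = pd.DataFrame({
        "gene_id": matrix.index,
        "embryo_id": embryo_id,
        "ratio": ratio,
        "p": p,
        "p_adj": p_adj,
        "direction": np.where(ratio > 1.0, "up", "down"),
        "de": p_adj < fdr,
        "cv_flag": cv.set_index("gene_id")["cv_flag"]
                     .reindex(matrix.index).to_numpy(),
    })
    return out.reset_index(drop=True)


def compute_cv(matrix: pd.DataFrame, group_ids: list[str],
               threshold: float = DEFAULT_CV_THRESHOLD) -> pd.DataFrame:
    """Coefficient of variation per gene within a sample group.

    Cv = sample SD / mean on the *linear* scale, reported in percent;
    genes whose linear mean is <= 0 get NaN with a warning.  ``matrix``
    holds log2 values, as everywhere in this package.
    """
    group_ids = list(group_ids)
    if len(group_ids) < 2:
        raise ValueError("need at least 2 samples to compute a Cv")
    linear = np.power(2.0, matrix[group_ids].to_numpy(dtype=float))
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    n_bad = int(np.sum(~(mean > 0)))
    if n_bad:
        warnings.warn(f"{n_bad} genes with non-positive mean; Cv set to NaN")
    return pd.DataFrame({
        "gene_id": matrix.index,
        "cv": cv,
        "cv_flag": np.where(np.isnan(cv), True, cv > threshold),
    }).reset_index(drop=True)


def summarize_direction(calls: pd.DataFrame) -> dict:
    """Up/down split of a DE call set: counts plus one-decimal percents.

    ``calls`` needs a ``direction`` column; rows are taken as the called
    genes of one comparison set.  Percentages are NaN for empty input.
    """
    n_total = len(calls)
    n_up = int((calls["direction"] == "up").sum()) if n_total else 0
    n_down = n_total - n_up
    if n_total:
        pct_up = round(100.0 * n_up / n_total, 1)
        pct_down = round(100.0 * n_down / n_total, 1)
    else:
        pct_up = pct_down = float("nan")
    return {"n_total": n_total, "n_up": n_up, "n_down": n_down,
            "pct_up": pct_up, "pct_down": pct_down}


class EmbryoDEModel:
    """Single-embryo DE model over an expression matrix.

    Parameters
    ----------
    matrix : genes x samples log2 expression.
    control_ids : columns forming the control-embryo pool.

    ``fit(embryo_id)`` returns :class:`DEResults` for one embryo;
    ``fit_all(embryo_ids)`` concatenates several comparisons (BH family
    stays within each embryo).
    """

    def __init__(self, matrix: pd.DataFrame, control_ids: list[str]):
        self.matrix = matrix
        self.control_ids = list(control_ids)

    def fit(self, embryo_id: str, fdr: float = DEFAULT_FDR) -> "DEResults":
        calls = de_single_embryo(self.matrix, embryo_id, self.control_ids,
                                 fdr=fdr)
        return DEResults(calls=calls, embryo_id=embryo_id, fdr=fdr)

    def fit_all(self, embryo_ids: list[str],
                fdr: float = DEFAULT_FDR) -> pd.DataFrame:
        return pd.concat([self.fit(e, fdr=fdr).calls for e in embryo_ids],
                         ignore_index=True)

    def control_cv(self) -> pd.DataFrame:
        return compute_cv(self.matrix, self.control_ids)


@dataclass
class DEResults:
    calls: pd.DataFrame
    embryo_id: str
    fdr: float

    @property
    def de_calls(self) -> pd.DataFrame:
        return self.calls[self.calls["de"]]

    def de_genes(self, direction: str | None = None) -> set[str]:
        c = self.de_calls
        if direction is not None:
            c = c[c["direction"] == direction]
        return set(c["gene_id"])

    def summary(self) -> dict:
        s = summarize_direction(self.de_calls)
        s["embryo_id"] = self.embryo_id
        s["fdr"] = self.fdr
        return s
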