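"""Relative quantification of validation qPCR by the delta-delta-Ct method.

Technical replicates are averaged first (arithmetic mean of Ct), each
sample's delta-Ct is Ct(target) - Ct(reference), and the fold change is
2^(mean dCt of group2 - mean dCt of group1), oriented so fold > 1 means
higher expression in group1.  PCR efficiency is assumed to be 100%
(fold-per-cycle exactly 2); no efficiency-corrected model is provided.
The p-value is a two-sided two-sample Student t on per-sample delta-Ct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FoldResult", "delta_delta_ct"]

REQUIRED_COLUMNS = ("sample_id", "group", "gene_id", "replicate", "ct")


@dataclass
class FoldResult:
    gene_id: str
    group1: str
    group2: str
    fold: float
    p: float
    delta_ct_group1: float
    delta_ct_group2: float
    n_group1: int
    n_group2: int

    def summary(self) -> str:
        return (f"{self.gene_id}: fold({self.group1}/{self.group2}) = "
                f"{self.fold:.3f}, p = {self.p:.3g} "
                f"(n = {self.n_group1}+{self.n_group2})")


def delta_delta_ct(table: pd.DataFrame, target_gene: str, ref_gene: str,
                   group1: str, group2: str) -> FoldResult:
    """Fold change of ``target_gene`` between two groups, normalized to a
    reference gene (e.g. Rn18s).

    ``table`` columns: sample_id, group, gene_id, replicate, ct (cycles,
    > 0).  With fewer than 2 samples in either group the fold is still
    reported but p is NaN.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    sub = table[table["group"].isin([group1, group2])
                & table["gene_id"].isin([target_gene, ref_gene])]
    # replicate mean per (sample, gene)
    means = (sub.groupby(["sample_id", "group", "gene_id"])["ct"]
                .mean().unstack("gene_id"))
    for gene in (target_gene, ref_gene):
        if gene not in means.columns or means[gene].isna().any():
            raise ValueError(
                f"gene {gene!r} not measured in every sample of both groups")
    dct = (means[target_gene] - means[ref_gene]).rename("delta_ct")
    groups = means.index.get_level_values("group")
    d1 = dct[groups == group1].to_numpy()
    d2 = dct[groups == group2].to_numpy()
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("both groups need at least one sample")
    fold = float(np.power(2.0, d2.mean() - d1.mean()))
    if len(d1) >= 2 and len(d2) >= 2:
        _, p = stats.ttest_ind(d1, d2, equal_var=True)
        p = float(p)
    else:
        p = float("nan")
    return FoldResult(gene_id=target_gene, group1=group1, group2=group2,
                      fold=fold, p=p,
                      delta_ct_group1=float(d1.mean()),
                      delta_ct_group2=float(d2.mean()),
                      n_group1=len(d1), n_group2=len(d2))
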