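"""Histone-association calling from MNase-fraction vs input tiling tracks.

Pipeline: RMA-style probe normalization (background percentile, quantile
normalization, log2) -> input subtraction (log2 MNase minus log2 genomic
input) -> per-probe T statistics -> MAT-style sliding-window score (10%
trimmed mean of probe statistics scaled by sqrt(n_probes), 600-bp windows,
100-bp step) -> significant-window merging into enriched/depleted regions
(p < 0.01) -> gene annotation by any-overlap (>0%) with the annotated gene
extent -> per-male MAT(+)/MAT(-) differential verdicts against controls.

Window p-values come from a seeded sign-flip permutation null when enough
structure is available, or from a Gaussian tail on robustly standardized
window scores (median/MAD) — the only option for 1-vs-1 male comparisons,
where label permutation is degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .simulate import GenomeModel

__all__ = [
    "ProbeTrack",
    "quantile_normalize",
    "normalize_probes",
    "input_subtract",
    "window_scores",
    "call_regions",
    "annotate_genes",
    "regions_to_bed6",
    "write_regions_bed",
    "differential_histone_calls",
    "feature_class_association",
    "TilingDifferential",
    "TilingDifferentialResults",
]

SIGNS = ("MAT+", "MAT-")


@dataclass
class ProbeTrack:
    """Probe coordinates plus a probes x samples value matrix.

    ``probes`` must be sorted by (chrom, start) with no zero-length
    probes; ``values`` is indexed by probe_id in the same order.
    """

    probes: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.probes
        if (p["end"] <= p["start"]).any():
            raise ValueError("zero- or negative-length probes present")
        key = p[["chrom", "start"]]
        if not (key.equals(key.sort_values(["chrom", "start"],
                                           kind="mergesort"))):
            order = np.lexsort((p["start"].to_numpy(),
                                p["chrom"].to_numpy()))
            self.probes = p.iloc[order].reset_index(drop=True)
            self.values = self.values.iloc[order]
        if not np.array_equal(self.probes["probe_id"].to_numpy(),
                              self.values.index.to_numpy()):
            self.values = self.values.reindex(self.probes["probe_id"])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "ProbeTrack":
        return ProbeTrack(probes=self.probes.copy(), values=values)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-wise means
    of the column-sorted matrix (ties receive the mean of the tied
    quantiles, as in the usual microarray implementation)."""
    x = values.to_numpy(dtype=float)
    n = x.shape[0]
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_probes(track: ProbeTrack,
                     background_percentile: float | None = None,
                     log2: bool = True) -> ProbeTrack:
    """RMA-style normalization of raw linear intensities.

    Optional per-sample background subtraction at the given percentile
    (values clipped to the smallest remaining positive value), quantile
    normalization across samples, then log2.  Columns named with a
    ``.<channel>`` suffix (e.g. ``.mnase`` / ``.input``) are quantile-
    normalized within their channel class only: the MNase fraction and
    the genomic input have genuinely different intensity distributions,
    and forcing them onto a common one would erase the enrichment signal.
    Raises on non-positive input intensities, naming offending probes.
    """
    vals = track.values
    bad = vals.index[(vals <= 0).any(axis=1)]
    if len(bad):
        shown = ", ".join(map(str, bad[:5]))
        raise ValueError(
            f"non-positive intensities for {len(bad)} probes (e.g. {shown})")
    x = vals.to_numpy(dtype=float).copy()
    if background_percentile is not None:
        bg = np.percentile(x, background_percentile, axis=0)
        x = x - bg[None, :]
        pos = x[x > 0]
        floor = pos.min() if pos.size else 1e-6
        x = np.clip(x, floor, None)
    frame = pd.DataFrame(x, index=vals.index, columns=vals.columns)
    channels: dict[str, list[str]] = {}
    for col in frame.columns:
        chan = col.rsplit(".", 1)[1] if "." in col else ""
        channels.setdefault(chan, []).append(col)
    normed = frame.copy()
    for cols in channels.values():
        normed[cols] = quantile_normalize(frame[cols])
    if log2:
        normed = np.log2(normed)
    return track.with_values(normed)


def input_subtract(track: ProbeTrack) -> ProbeTrack:
    """log2(MNase) - log2(input) per probe, pairing ``<male>.mnase`` with
    ``<male>.input`` columns; the output has one column per male."""
    cols = track.values.columns
    males = [c[:-len(".mnase")] for c in cols if c.endswith(".mnase")]
    if not males:
        raise ValueError("no '.mnase' channels found")
    missing = [m for m in males if f"{m}.input" not in cols]
    if missing:
        raise ValueError(f"missing input channel for: {', '.join(missing)}")
    out = pd.DataFrame(
        {m: track.values[f"{m}.mnase"] - track.values[f"{m}.input"]
         for m in males},
        index=track.values.index)
    return track.with_values(out)


# ---------------------------------------------------------------------------
# window machinery

@dataclass
class _WindowIndex:
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    lo: np.ndarray  # first probe (positional) overlapping each window
    hi: np.ndarray  # one past last probe overlapping each window
    n: np.ndarray

    def members(self, i: int) -> np.ndarray:
        return np.arange(self.lo[i], self.hi[i])


def _build_window_index(probes: pd.DataFrame, window: int, step: int,
                        min_probes: int) -> _WindowIndex:
    chrom_arr, start_arr, end_arr = [], [], []
    lo_arr, hi_arr = [], []
    starts_all = probes["start"].to_numpy()
    ends_all = probes["end"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        starts = starts_all[idx]
        ends = ends_all[idx]
        w0 = int(starts[0])
        wlast = int(ends.max()) - window
        wstarts = np.arange(w0, max(w0, wlast) + 1, step)
        if not np.all(np.diff(ends) >= 0):
            # only fixed-length (or non-nested) tiling probes supported:
            # window membership must be a contiguous probe run
            raise ValueError(
                f"probe ends not monotone on {chrom}; irregular probe "
                "geometry is unsupported")
        lo = np.searchsorted(ends, wstarts, side="right")
        hi = np.searchsorted(starts, wstarts + window, side="left")
        n = hi - lo
        keep = n >= min_probes
        chrom_arr.append(np.full(keep.sum(), chrom, dtype=object))
        start_arr.append(wstarts[keep])
        end_arr.append(wstarts[keep] + window)
        lo_arr.append(idx[0] + lo[keep])
        hi_arr.append(idx[0] + hi[keep])
    cat = lambda xs, dt: (np.concatenate(xs) if xs else np.array([], dtype=dt))
    lo = cat(lo_arr, int)
    hi = cat(hi_arr, int)
    return _WindowIndex(chrom=cat(chrom_arr, object),
                        start=cat(start_arr, int), end=cat(end_arr, int),
                        lo=lo, hi=hi, n=hi - lo)


def window_probe_members(track: ProbeTrack, window: int = 600,
                         step: int = 100, min_probes: int = 1) -> list[tuple]:
    """(chrom, start, end, [probe ids]) per window — the raw membership
    used by the scorer, exposed for direct inspection."""
    wi = _build_window_index(track.probes, window, step, min_probes)
    ids = track.probes["probe_id"].to_numpy()
    return [(wi.chrom[i], int(wi.start[i]), int(wi.end[i]),
             list(ids[wi.lo[i]:wi.hi[i]])) for i in range(len(wi.n))]


def _probe_statistics(values: pd.DataFrame, group_a: list[str],
                      group_b: list[str]) -> np.ndarray:
    """Per-probe two-sample T statistic of group_a vs group_b.

    With >=2 samples per group this is a Welch t; with single samples the
    statistic is the per-probe difference standardized by a robust global
    scale (MAD of all differences), the only estimable analogue.
    """
    A = values[list(group_a)].to_numpy(dtype=float)
    B = values[list(group_b)].to_numpy(dtype=float)
    if A.shape[1] >= 2 and B.shape[1] >= 2:
        t, _ = stats.ttest_ind(A, B, axis=1, equal_var=False)
        return np.nan_to_num(t)
    d = A.mean(axis=1) - B.mean(axis=1)
    mad = stats.median_abs_deviation(d, scale="normal")
    scale = mad if mad > 0 else d.std(ddof=1)
    if not np.isfinite(scale) or scale == 0:
        return d
    return d / scale


def _score_windows(statistics: np.ndarray, wi: _WindowIndex,
                   trim: float = 0.1) -> np.ndarray:
    """Trimmed-mean of member probe statistics scaled by sqrt(n)."""
    csum = np.concatenate([[0.0], np.cumsum(statistics)])
    n = wi.n
    mean = (csum[wi.hi] - csum[wi.lo]) / np.maximum(n, 1)
    k = (trim * n).astype(int)
    scores = mean * np.sqrt(n)
    for i in np.flatnonzero(k > 0):
        vals = np.sort(statistics[wi.lo[i]:wi.hi[i]])
        trimmed = vals[k[i]:len(vals) - k[i]]
        scores[i] = trimmed.mean() * np.sqrt(n[i])
    return scores


def _gaussian_p(scores: np.ndarray) -> np.ndarray:
    """Two-sided tail p from robustly standardized window scores."""
    med = np.median(scores)
    mad = stats.median_abs_deviation(scores, scale="normal")
    scale = mad if mad > 0 else scores.std()
    if not np.isfinite(scale) or scale == 0:
        return np.ones_like(scores)
    z = (scores - med) / scale
    return np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)


def _signflip_p(statistics: np.ndarray, wi: _WindowIndex,
                observed: np.ndarray, n_permutations: int,
                rng: np.random.Generator, trim: float = 0.1) -> np.ndarray:
    """Pooled two-sided permutation p: probe statistics are randomly
    sign-flipped, windows rescored, and all null |scores| pooled."""
    order = np.argsort(np.abs(observed))
    obs_sorted = np.abs(observed)[order]
    count_ge = np.zeros(len(observed), dtype=np.int64)
    total = 0
    for _ in range(n_permutations):
        signs = rng.integers(0, 2, size=len(statistics)) * 2 - 1
        null = np.abs(_score_windows(statistics * signs, wi, trim))
        null.sort()
        total += null.size
        count_ge[order] += null.size - np.searchsorted(null, obs_sorted,
                                                       side="left")
    return (1.0 + count_ge) / (1.0 + total)


def window_scores(track: ProbeTrack, group_a: list[str], group_b: list[str],
                  window: int = 600, step: int = 100, min_probes: int = 4,
                  null_method: str = "auto", n_permutations: int = 1000,
                  seed: int = 0, trim: float = 0.1,
                  _index: _WindowIndex | None = None) -> pd.DataFrame:
    """MAT-style window scores of group_a vs group_b on a log-ratio track.

    Returns a window table (chrom, start, end, n_probes, score, p) sorted
    by (chrom, start).  ``null_method``: "permutation" (seeded sign
    flips), "gaussian" (robust-z tail), or "auto" (permutation when both
    groups have >=2 samples, gaussian otherwise).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both comparison groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("comparison groups overlap")
    wi = _index if _index is not None else _build_window_index(
        track.probes, window, step, min_probes)
    statistics = _probe_statistics(track.values, group_a, group_b)
    scores = _score_windows(statistics, wi, trim)
    if null_method == "auto":
        null_method = ("permutation"
                       if len(group_a) >= 2 and len(group_b) >= 2
                       else "gaussian")
    if len(scores) == 0:
        p = np.array([])
    elif null_method == "gaussian":
        p = _gaussian_p(scores)
    elif null_method == "permutation":
        rng = np.random.default_rng(seed)
        p = _signflip_p(statistics, wi, scores, n_permutations, rng, trim)
    else:
        raise ValueError(f"unknown null_method {null_method!r}")
    return pd.DataFrame({"chrom": wi.chrom, "start": wi.start,
                         "end": wi.end, "n_probes": wi.n,
                         "score": scores, "p": p})


def call_regions(scores: pd.DataFrame, p_threshold: float = 0.01,
                 merge_gap: int = 300) -> pd.DataFrame:
    """Merge significant same-sign windows within ``merge_gap`` bp into
    non-overlapping regions; region p is the minimum window p, region
    score the extreme window score, direction the common sign."""
    sig = scores[(scores["p"] < p_threshold) & (scores["score"] != 0)]
    sig = sig.sort_values(["chrom", "start"], kind="mergesort")
    regions = []
    # each sign stratum merges independently: an intervening window of the
    # opposite sign does not break a same-sign chain
    for sign, positive in (("+", True), ("-", False)):
        sub = sig[(sig["score"] > 0) == positive]
        cur = None
        for row in sub.itertuples(index=False):
            if (cur is not None and row.chrom == cur["chrom"]
                    and row.start - cur["end"] <= merge_gap):
                cur["end"] = max(cur["end"], row.end)
                if abs(row.score) > abs(cur["score"]):
                    cur["score"] = row.score
                cur["p"] = min(cur["p"], row.p)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": row.chrom, "start": row.start,
                       "end": row.end, "score": row.score, "p": row.p,
                       "direction": sign}
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "score",
                                         "p", "direction"])
    return out.sort_values(["chrom", "start"],
                           kind="mergesort").reset_index(drop=True)


def annotate_genes(regions: pd.DataFrame, genome: GenomeModel,
                   male_id: str | None = None) -> pd.DataFrame:
    """Assign regions to genes by any overlap (>0%) with the annotated
    gene extent (promoter union gene body), half-open coordinates.

    Returns one row per (gene, sign): gene_id, sign (MAT+/MAT-),
    best_score, p (minimum over supporting regions).
    """
    extents = genome.extents()
    trees: dict[str, IntervalTree] = {}
    for row in extents.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.gene_id)
    best: dict[tuple[str, str], dict] = {}
    for row in regions.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            warnings.warn(f"region on unknown chromosome {row.chrom!r}; "
                          "skipped")
            continue
        sign = "MAT+" if row.direction == "+" else "MAT-"
        for iv in tree.overlap(row.start, row.end):
            key = (iv.data, sign)
            rec = best.get(key)
            if rec is None:
                best[key] = {"gene_id": iv.data, "sign": sign,
                             "best_score": row.score, "p": row.p}
            else:
                if abs(row.score) > abs(rec["best_score"]):
                    rec["best_score"] = row.score
                rec["p"] = min(rec["p"], row.p)
    calls = pd.DataFrame(sorted(best.values(),
                                key=lambda r: (r["gene_id"], r["sign"])),
                         columns=["gene_id", "sign", "best_score", "p"])
    if male_id is not None:
        calls.insert(1, "male_id", male_id)
    return calls


def regions_to_bed6(regions: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a region table: name = direction, score = window
    score x100 (integer), strand '.'."""
    return pd.DataFrame({
        "chrom": regions["chrom"], "start": regions["start"],
        "end": regions["end"], "name": regions["direction"],
        "score": (regions["score"] * 100).round().astype(int),
        "strand": ".",
    })


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    regions_to_bed6(regions).to_csv(path, sep="\t", header=False,
                                    index=False)


def differential_histone_calls(track: ProbeTrack, genome: GenomeModel,
                               samples: list[str], controls: list[str],
                               mode: str = "single_vs_each_control",
                               window: int = 600, step: int = 100,
                               min_probes: int = 4, p_threshold: float = 0.01,
                               merge_gap: int = 300,
                               null_method: str = "auto",
                               n_permutations: int = 1000,
                               seed: int = 0,
                               region_sink: dict | None = None
                               ) -> dict[str, pd.DataFrame]:
    """Per-male MAT(+)/MAT(-) differential gene calls vs controls.

    ``track`` is a log-ratio track (one column per male).  In single
    mode each sample male is compared pairwise against every individual
    control; a gene is differentially called with a given sign only if
    that sign is called in *every* pairwise comparison (intersection
    across controls).  In "all_vs_all" mode one pooled comparison of the
    sample group against the control group is made (key ``"all"``).
    """
    if not controls:
        raise ValueError("at least one control male is required")
    kw = dict(window=window, step=step, min_probes=min_probes,
              null_method=null_method, n_permutations=n_permutations)
    index = _build_window_index(track.probes, window, step, min_probes)

    def _calls(group_a, group_b, seed_off, key):
        scores = window_scores(track, group_a, group_b, seed=seed + seed_off,
                               _index=index, **kw)
        regions = call_regions(scores, p_threshold=p_threshold,
                               merge_gap=merge_gap)
        if region_sink is not None:
            region_sink[key] = regions
        return annotate_genes(regions, genome)

    results: dict[str, pd.DataFrame] = {}
    if mode == "single_vs_each_control":
        for si, male in enumerate(samples):
            per_control = [_calls([male], [ctl], seed_off=si * 1000 + ci,
                                  key=f"{male}_vs_{ctl}")
                           for ci, ctl in enumerate(controls)]
            merged = []
            for sign in SIGNS:
                sets = [set(c.loc[c["sign"] == sign, "gene_id"])
                        for c in per_control]
                common = set.intersection(*sets) if sets else set()
                for gene in sorted(common):
                    rows = [c[(c["gene_id"] == gene) & (c["sign"] == sign)]
                            for c in per_control]
                    merged.append({
                        "gene_id": gene, "male_id": male, "sign": sign,
                        "best_score": min(
                            (r["best_score"].iloc[0] for r in rows),
                            key=abs),
                        "p": max(r["p"].iloc[0] for r in rows),
                    })
            results[male] = pd.DataFrame(
                merged, columns=["gene_id", "male_id", "sign",
                                 "best_score", "p"])
    elif mode == "all_vs_all":
        calls = _calls(list(samples), list(controls), seed_off=0,
                       key="all")
        calls.insert(1, "male_id", "all")
        results["all"] = calls
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return results


def feature_class_association(track: ProbeTrack, genome: GenomeModel,
                              classes: str = "feature") -> pd.DataFrame:
    """Wilcoxon rank-sum association of MNase log-ratio with feature or
    sequence classes.

    ``classes``: "feature" compares probe-level enrichment between
    promoter and gene-body (CDS) probes; "gc_class", "cpg_class" or
    "methylation" compare gene-level mean enrichment between the
    corresponding gene classes (methylation is split at its median into
    low/high).  Degenerate classes (<2 members) yield NaN p.
    """
    enrich = track.values.mean(axis=1)
    if classes == "feature":
        if "feature" not in track.probes.columns:
            raise ValueError("probe table has no 'feature' column")
        labels = track.probes.set_index("probe_id")["feature"]
        values = enrich
    else:
        gene_col = track.probes.set_index("probe_id")["gene_id"]
        per_gene = enrich.groupby(gene_col).mean()
        genes = genome.genes.set_index("gene_id")
        if classes == "methylation":
            meth = genes["methylation"]
            labels = pd.Series(np.where(meth > meth.median(),
                                        "high_meth", "low_meth"),
                               index=genes.index)
        elif classes in ("gc_class", "cpg_class"):
            labels = genes[classes]
        else:
            raise ValueError(f"unknown class scheme {classes!r}")
        labels = labels.reindex(per_gene.index)
        values = per_gene
    groups = {lab: values[labels == lab].to_numpy()
              for lab in sorted(labels.dropna().unique())}
    if len(groups) < 2:
        raise ValueError("need at least two classes with members")
    rows = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if len(a) < 2 or len(b) < 2:
                u = p = np.nan
            else:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"class_a": names[i], "class_b": names[j],
                         "n_a": len(a), "n_b": len(b),
                         "median_a": float(np.median(a)) if len(a) else np.nan,
                         "median_b": float(np.median(b)) if len(b) else np.nan,
                         "statistic": u, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-style front end

class TilingDifferential:
    """Differential histone-association model for a normalized log-ratio
    track: sample males vs control males on a shared gene annotation.

    Examples
    --------
    >>> model = TilingDifferential(track, genome, samples, controls)
    >>> res = model.fit()
    >>> res.summary()          # per-male MAT+/- gene counts
    >>> res.gene_sets("prt1")  # {"MAT+": {...}, "MAT-": {...}}
    """

    def __init__(self, track: ProbeTrack, genome: GenomeModel,
                 samples: list[str], controls: list[str]):
        self.track = track
        self.genome = genome
        self.samples = list(samples)
        self.controls = list(controls)

    def fit(self, mode: str = "single_vs_each_control",
            **kwargs) -> "TilingDifferentialResults":
        calls = differential_histone_calls(
            self.track, self.genome, self.samples, self.controls,
            mode=mode, **kwargs)
        return TilingDifferentialResults(calls=calls, mode=mode)


@dataclass
class TilingDifferentialResults:
    calls: dict[str, pd.DataFrame]
    mode: str

    def gene_sets(self, male_id: str) -> dict[str, set[str]]:
        c = self.calls[male_id]
        out = {s: set(c.loc[c["sign"] == s, "gene_id"]) for s in SIGNS}
        out["MAT-/+"] = out["MAT+"] | out["MAT-"]
        return out

    def to_frame(self) -> pd.DataFrame:
        if not self.calls:
            return pd.DataFrame(columns=["gene_id", "male_id", "sign",
                                         "best_score", "p"])
        return pd.concat(self.calls.values(), ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Per-male counts of MAT+, MAT- and total differential genes."""
        rows = []
        for male, c in self.calls.items():
            plus = set(c.loc[c["sign"] == "MAT+", "gene_id"])
            minus = set(c.loc[c["sign"] == "MAT-", "gene_id"])
            rows.append({"male_id": male, "total_genes": len(plus | minus),
                         "mat_plus": len(plus), "mat_minus": len(minus)})
        return pd.DataFrame(rows)
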