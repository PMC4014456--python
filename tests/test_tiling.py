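"""Window scoring, normalization and gene-annotation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import histolink as hl
from histolink.simulate import GenomeModel
from histolink.tiling import window_probe_members


def make_track(starts, values, length=25, chrom="chr1", columns=None):
    starts = np.asarray(starts)
    order = np.argsort(starts, kind="mergesort")
    starts = starts[order]
    values = np.asarray(values, dtype=float)[order]
    probes = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + length,
        "probe_id": [f"p{i}" for i in range(len(starts))]})
    if values.ndim == 1:
        values = values[:, None]
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, columns=columns,
                        index=pd.Index(probes["probe_id"], name="probe_id"))
    return hl.ProbeTrack(probes=probes, values=vals)


def toy_genome(rows):
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom",
                                        "promoter_start", "promoter_end",
                                        "cds_start", "cds_end"])
    genes["strand"] = "+"
    genes["tss"] = genes["promoter_end"]
    chrom_lengths = {c: int(genes.loc[genes["chrom"] == c, "cds_end"].max()
                            + 1000) for c in set(genes["chrom"])}
    return GenomeModel(genes=genes, chrom_lengths=chrom_lengths)


class TestQuantileNormalize:
    def test_fixed_point_on_identical_multisets(self):
        rng = np.random.default_rng(0)
        a = rng.random(30)
        b = rng.permutation(a)
        df = pd.DataFrame({"a": a, "b": b})
        out = hl.quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_linear_scaling_collapses(self):
        rng = np.random.default_rng(1)
        a = rng.random(50) + 0.1
        df = pd.DataFrame({"a": a, "b": 2.0 * a})
        out = hl.quantile_normalize(df)
        np.testing.assert_allclose(out["a"], out["b"])

    def test_hand_computed_oracle(self):
        # classic 5x2 example: rank each column, average sorted rows
        df = pd.DataFrame({"a": [5.0, 2.0, 3.0, 4.0, 1.0],
                           "b": [4.0, 1.0, 4.5, 2.0, 3.0]})
        sorted_means = (np.sort(df["a"]) + np.sort(df["b"])) / 2.0
        expect_a = sorted_means[stats.rankdata(df["a"]).astype(int) - 1]
        expect_b = sorted_means[stats.rankdata(df["b"]).astype(int) - 1]
        out = hl.quantile_normalize(df)
        np.testing.assert_allclose(out["a"], expect_a)
        np.testing.assert_allclose(out["b"], expect_b)

    def test_normalize_rejects_nonpositive(self):
        track = make_track([0, 100], [[1.0, 2.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="p1"):
            hl.normalize_probes(track)


class TestInputSubtract:
    def test_identical_channels_zero_and_offset_one(self):
        rng = np.random.default_rng(2)
        v = rng.random(10) + 1
        track = make_track(np.arange(10) * 100, np.c_[v, v],
                           columns=["m.mnase", "m.input"])
        out = hl.input_subtract(track)
        np.testing.assert_allclose(out.values["m"], 0.0)
        track2 = make_track(np.arange(10) * 100, np.c_[v + 1, v],
                            columns=["m.mnase", "m.input"])
        np.testing.assert_allclose(hl.input_subtract(track2).values["m"], 1.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(10), rng.random(10)
        track = make_track(np.arange(10) * 100, np.c_[a, b],
                           columns=["m.mnase", "m.input"])
        np.testing.assert_allclose(hl.input_subtract(track).values["m"],
                                   a - b)

    def test_missing_pair_raises(self):
        track = make_track([0], [[1.0]], columns=["m.mnase"])
        with pytest.raises(ValueError, match="input"):
            hl.input_subtract(track)


class TestWindows:
    def test_membership_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(np.arange(0, 5000, 25), size=50,
                                    replace=False))
        track = make_track(starts, rng.normal(size=(50, 2)))
        window, step = 600, 100
        got = window_probe_members(track, window=window, step=step,
                                   min_probes=1)
        probes = track.probes
        w0 = int(probes["start"].min())
        expected = []
        for ws in range(w0, int(probes["end"].max()) - window + 1, step):
            members = [r.probe_id for r in probes.itertuples()
                       if r.end > ws and r.start < ws + window]
            if members:
                expected.append((ws, members))
        got_nonempty = [(s, m) for _, s, _, m in got if m]
        assert got_nonempty == expected

    def test_null_identity(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=30)
        track = make_track(np.arange(30) * 50, np.c_[v, v],
                           columns=["a", "b"])
        scores = hl.window_scores(track, ["a"], ["b"], min_probes=2)
        assert (scores["score"] == 0).all()
        assert (scores["p"] > 0.9).all()

    def test_noise_free_injected_shift_is_peak(self):
        n = 60
        starts = np.arange(n) * 50
        a = np.zeros(n)
        span = (starts >= 1000) & (starts < 1600)
        a[span] = 1.0
        track = make_track(starts, np.c_[a, np.zeros(n)],
                           columns=["a", "b"])
        scores = hl.window_scores(track, ["a"], ["b"], min_probes=2)
        best = scores.loc[scores["score"].idxmax()]
        assert best["score"] > 0
        assert best["start"] == 1000
        full = scores[(scores["start"] >= 1000) & (scores["end"] <= 1600)]
        assert (scores["score"] <= best["score"] + 1e-12).all()
        assert len(full) and (full["score"] > 0).all()

    def test_sign_symmetry(self):
        rng = np.random.default_rng(6)
        track = make_track(np.arange(40) * 50, rng.normal(size=(40, 2)),
                           columns=["a", "b"])
        fwd = hl.window_scores(track, ["a"], ["b"], min_probes=2)
        rev = hl.window_scores(track, ["b"], ["a"], min_probes=2)
        np.testing.assert_allclose(fwd["score"], -rev["score"])

    def test_group_mode_uses_welch_and_permutation(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(40, 6)) * 0.2
        base[10:22, :3] += 2.0  # shifted span in group A only
        track = make_track(np.arange(40) * 50, base,
                           columns=list("abcdef"))
        scores = hl.window_scores(track, ["a", "b", "c"], ["d", "e", "f"],
                                  min_probes=2, n_permutations=200, seed=0)
        hit = scores[(scores["start"] >= 500) & (scores["end"] <= 1100)]
        assert (hit["p"] < 0.05).all()

    def test_disjoint_group_validation(self):
        track = make_track([0, 50], [[1.0, 2.0], [3.0, 4.0]],
                           columns=["a", "b"])
        with pytest.raises(ValueError):
            hl.window_scores(track, ["a"], ["a"])
        with pytest.raises(ValueError):
            hl.window_scores(track, [], ["a"])


def brute_force_merge(rows, merge_gap):
    """Independent O(n^2) merge oracle over significant windows."""
    clusters = []
    for row in rows:
        sign = "+" if row["score"] > 0 else "-"
        placed = False
        for cl in clusters:
            if (cl["chrom"] == row["chrom"] and cl["direction"] == sign
                    and row["start"] - cl["end"] <= merge_gap
                    and cl["start"] - row["end"] <= merge_gap):
                cl["start"] = min(cl["start"], row["start"])
                cl["end"] = max(cl["end"], row["end"])
                cl["p"] = min(cl["p"], row["p"])
                if abs(row["score"]) > abs(cl["score"]):
                    cl["score"] = row["score"]
                placed = True
                break
        if not placed:
            clusters.append({**row, "direction": sign})
    return clusters


class TestCallRegions:
    def test_none_significant_gives_empty(self):
        scores = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [600],
                               "n_probes": [4], "score": [1.0], "p": [0.5]})
        assert hl.call_regions(scores).empty

    def test_adjacent_windows_merge(self):
        scores = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 200],
            "end": [600, 800], "n_probes": [4, 4],
            "score": [3.0, 4.0], "p": [0.001, 0.0005]})
        regions = hl.call_regions(scores, merge_gap=300)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start"], r["end"], r["score"], r["p"], r["direction"]) == \
            (0, 800, 4.0, 0.0005, "+")

    def test_opposite_signs_do_not_merge(self):
        scores = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 200],
            "end": [600, 800], "n_probes": [4, 4],
            "score": [3.0, -4.0], "p": [0.001, 0.0005]})
        assert len(hl.call_regions(scores, merge_gap=300)) == 2

    def test_randomized_merge_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(3, 15)
            starts = np.sort(rng.choice(np.arange(0, 6000, 100), size=n,
                                        replace=False))
            scores = pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], size=n),
                "start": starts, "end": starts + 600,
                "n_probes": 4,
                "score": rng.normal(size=n) * 3,
                "p": rng.random(n) * 0.02})
            got = hl.call_regions(scores, p_threshold=0.01, merge_gap=300)
            sig = scores[scores["p"] < 0.01].sort_values(["chrom", "start"])
            expected = brute_force_merge(
                [r._asdict() for r in sig.itertuples(index=False)], 300)
            assert len(got) == len(expected)
            for g, e in zip(got.itertuples(index=False), expected):
                assert (g.chrom, g.start, g.end, g.direction) == \
                    (e["chrom"], e["start"], e["end"], e["direction"])


class TestAnnotateGenes:
    def test_region_between_genes_no_call(self):
        genome = toy_genome([("g1", "chr1", 0, 100, 100, 200),
                             ("g2", "chr1", 500, 600, 600, 700)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [250],
                                "end": [450], "score": [3.0], "p": [0.001],
                                "direction": ["+"]})
        assert hl.annotate_genes(regions, genome).empty

    def test_halfopen_boundary(self):
        genome = toy_genome([("g1", "chr1", 1000, 1100, 1100, 1200)])
        # region ending exactly at the gene start: no overlap (half-open)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [800],
                                "end": [1000], "score": [3.0], "p": [0.001],
                                "direction": ["+"]})
        assert hl.annotate_genes(regions, genome).empty
        regions.loc[0, "end"] = 1001  # 1-bp overlap counts
        calls = hl.annotate_genes(regions, genome)
        assert list(calls["gene_id"]) == ["g1"]
        assert list(calls["sign"]) == ["MAT+"]

    def test_unknown_chrom_warns_and_skips(self):
        genome = toy_genome([("g1", "chr1", 0, 100, 100, 200)])
        regions = pd.DataFrame({"chrom": ["chrX"], "start": [0],
                                "end": [100], "score": [1.0], "p": [0.001],
                                "direction": ["+"]})
        with pytest.warns(UserWarning, match="chrX"):
            assert hl.annotate_genes(regions, genome).empty

    def test_allpairs_overlap_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(30):
            s = int(rng.integers(0, 20_000))
            rows.append((f"g{i:02d}", "chr1", s, s + 300, s + 300, s + 800))
        genome = toy_genome(rows)
        starts = rng.integers(0, 20_000, size=20)
        regions = pd.DataFrame({
            "chrom": "chr1", "start": starts,
            "end": starts + rng.integers(50, 1500, size=20),
            "score": rng.normal(size=20) * 3,
            "p": rng.random(20) * 0.01})
        regions["direction"] = np.where(regions["score"] > 0, "+", "-")
        calls = hl.annotate_genes(regions, genome)
        got = set(zip(calls["gene_id"], calls["sign"]))
        expected = set()
        for g in rows:
            g_start, g_end = g[2], g[5]
            for r in regions.itertuples(index=False):
                if r.start < g_end and g_start < r.end:
                    sign = "MAT+" if r.direction == "+" else "MAT-"
                    expected.add((g[0], sign))
        assert got == expected


class TestDifferential:
    def test_identical_sample_gives_empty(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=60)
        track = make_track(np.arange(60) * 50, np.c_[v, v, v],
                           columns=["s", "c1", "c2"])
        genome = toy_genome([("g1", "chr1", 0, 1500, 1500, 3000)])
        calls = hl.differential_histone_calls(track, genome, ["s"],
                                              ["c1", "c2"])
        assert calls["s"].empty

    def test_zero_controls_raises(self):
        rng = np.random.default_rng(11)
        track = make_track(np.arange(10) * 50, rng.normal(size=(10, 1)),
                           columns=["s"])
        genome = toy_genome([("g1", "chr1", 0, 250, 250, 500)])
        with pytest.raises(ValueError):
            hl.differential_histone_calls(track, genome, ["s"], [])

    def test_recovery_on_synthetic_truth(self, recovery_study,
                                         recovery_calls):
        study = recovery_study
        total = recovered = 0
        for m in study.perturbed_males:
            truth = study.true_gene_sets(m)
            rec = recovery_calls.gene_sets(m)
            for sign in ("MAT+", "MAT-"):
                total += len(truth[sign])
                recovered += len(truth[sign] & rec[sign])
        assert recovered / total >= 0.90

    def test_monotonicity_in_shift(self):
        """A larger injected occupancy shift never recovers fewer
        true-positive genes (same seed, same noise)."""
        hits = []
        for shift in (0.5, 1.5, 3.0):
            cfg = hl.SimulationConfig(seed=21, n_genes=300,
                                      occupancy_shift=shift)
            study = hl.simulate_study(cfg)
            track = hl.ProbeTrack(probes=study.probes,
                                  values=study.intensities)
            ratio = hl.input_subtract(hl.normalize_probes(track))
            res = hl.TilingDifferential(
                ratio, study.genome, study.perturbed_males,
                study.control_males).fit()
            tp = 0
            for m in study.perturbed_males:
                truth = study.true_gene_sets(m)
                rec = res.gene_sets(m)
                tp += sum(len(truth[s] & rec[s]) for s in ("MAT+", "MAT-"))
            hits.append(tp)
        assert hits == sorted(hits)

    def test_all_vs_all_contains_consistent_per_male_calls(self):
        # males share most aberrant genes so the pooled comparison must
        # recover what every pairwise comparison agrees on
        cfg = hl.SimulationConfig(seed=22, n_genes=200,
                                  frac_mat_plus_genes=0.45,
                                  frac_mat_minus_genes=0.45)
        study = hl.simulate_study(cfg)
        track = hl.ProbeTrack(probes=study.probes, values=study.intensities)
        ratio = hl.input_subtract(hl.normalize_probes(track))
        model = hl.TilingDifferential(ratio, study.genome,
                                      study.perturbed_males,
                                      study.control_males)
        single = model.fit(mode="single_vs_each_control")
        pooled = model.fit(mode="all_vs_all", n_permutations=200)
        pooled_sets = pooled.gene_sets("all")
        for sign in ("MAT+", "MAT-"):
            common = set.intersection(*(single.gene_sets(m)[sign]
                                        for m in study.perturbed_males))
            if common:
                frac = len(common & pooled_sets[sign]) / len(common)
                assert frac >= 0.8, (sign, frac)


class TestFeatureClasses:
    def test_identical_distributions_p_near_one(self):
        v = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        probes = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(8) * 100,
            "end": np.arange(8) * 100 + 25,
            "probe_id": [f"p{i}" for i in range(8)],
            "gene_id": "g1",
            "feature": ["promoter"] * 4 + ["cds"] * 4})
        vals = pd.DataFrame({"s": v},
                            index=pd.Index(probes["probe_id"],
                                           name="probe_id"))
        track = hl.ProbeTrack(probes=probes, values=vals)
        genome = toy_genome([("g1", "chr1", 0, 400, 400, 825)])
        rep = hl.feature_class_association(track, genome, classes="feature")
        assert rep["p"].iloc[0] > 0.9

    def test_promoter_enrichment_on_synthetic_genome(self, recovery_study):
        study = recovery_study
        track = hl.ProbeTrack(probes=study.probes, values=study.intensities)
        ratio = hl.input_subtract(hl.normalize_probes(track))
        rep = hl.feature_class_association(ratio, study.genome,
                                           classes="feature")
        row = rep.iloc[0]
        pair = {row["class_a"]: row["median_a"],
                row["class_b"]: row["median_b"]}
        assert pair["promoter"] > pair["cds"]
        assert row["p"] < 1e-3

    def test_exact_enumeration_oracle_4v4(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 0.5
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        center = 4 * 9 / 2.0
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for combo in combos:
            s = ranks[list(combo)].sum()
            if abs(s - center) >= abs(obs - center) - 1e-9:
                count += 1
        p_oracle = count / len(combos)
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact")
        assert p == pytest.approx(p_oracle, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_sign_symmetry_property(seed):
    """Swapping the comparison groups negates every window score."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 40))
    track = make_track(np.sort(rng.choice(np.arange(0, 4000, 50), size=n,
                                          replace=False)),
                       rng.normal(size=(n, 2)), columns=["a", "b"])
    fwd = hl.window_scores(track, ["a"], ["b"], min_probes=2)
    rev = hl.window_scores(track, ["b"], ["a"], min_probes=2)
    np.testing.assert_allclose(fwd["score"].to_numpy(),
                               -rev["score"].to_numpy(), atol=1e-9)
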