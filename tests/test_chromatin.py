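import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from stemsig import chromatin as ch
from stemsig import synthetic_data as sd


def pc(intervals, scores=None, summits=None):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    if scores is not None:
        df["score"] = scores
    if summits is not None:
        df["summit"] = summits
    return ch.PeakCollection(df)


class TestPeakCollection:
    def test_validates_coordinates(self):
        with pytest.raises(ValueError, match="start >= end"):
            pc([("chr1", 10, 10)])
        with pytest.raises(ValueError, match="summit outside"):
            pc([("chr1", 10, 20)], summits=[25])

    def test_bed_round_trip(self, tmp_path):
        p = pc([("chr1", 10, 30), ("chr2", 5, 25)], scores=[7.0, 3.0])
        path = tmp_path / "x.bed"
        p.to_bed(path)
        q = ch.PeakCollection.from_bed(path)
        assert q.df[["chrom", "start", "end", "summit"]].equals(
            p.df[["chrom", "start", "end", "summit"]]
        )

    def test_malformed_bed_reports_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\nchr1\tnope\t30\n")
        with pytest.raises(ValueError, match="line 2"):
            ch.PeakCollection.from_bed(path)

    def test_narrowpeak_summit_offset(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text(
            "chr1\t100\t300\tp1\t0\t.\t5.0\t1\t1\t50\n"
            "chr1\t400\t500\tp2\t0\t.\t2.0\t1\t1\t-1\n"
        )
        q = ch.PeakCollection.from_narrowpeak(path)
        assert q.df["summit"].tolist() == [150, 450]  # offset vs midpoint


class TestMergeUnion:
    def test_bookended_intervals_merge(self):
        u = ch.merge_peak_union([pc([("chr1", 10, 20), ("chr1", 20, 30)])])
        assert u.df[["start", "end"]].values.tolist() == [[10, 30]]

    def test_disjoint_inputs_unchanged(self):
        p = pc([("chr1", 10, 20), ("chr1", 30, 40), ("chr2", 5, 8)])
        u = ch.merge_peak_union([p])
        assert u.df[["chrom", "start", "end"]].values.tolist() == \
            p.df[["chrom", "start", "end"]].values.tolist()

    def test_summit_from_highest_scoring_peak(self):
        a = pc([("chr1", 10, 30)], scores=[5.0], summits=[15])
        b = pc([("chr1", 25, 50)], scores=[9.0], summits=[40])
        u = ch.merge_peak_union([a, b])
        assert u.df["summit"].tolist() == [40]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 5000, size=200)
        p = pc([("chr1", s, s + rng.integers(10, 100)) for s in starts])
        u1 = ch.merge_peak_union([p])
        u2 = ch.merge_peak_union([u1])
        assert u1.df[["chrom", "start", "end"]].equals(
            u2.df[["chrom", "start", "end"]]
        )

    def test_matches_boolean_mask_oracle(self):
        rng = np.random.default_rng(1)
        intervals = []
        mask = np.zeros(20000, dtype=bool)
        for _ in range(1000):
            s = int(rng.integers(0, 19000))
            e = s + int(rng.integers(1, 800))
            intervals.append(("chr1", s, min(e, 20000)))
            mask[s:min(e, 20000)] = True
        u = ch.merge_peak_union([pc(intervals)])
        union_len = int((u.df["end"] - u.df["start"]).sum())
        assert union_len == int(mask.sum())
        got = np.zeros(20000, dtype=bool)
        for r in u.df.itertuples():
            # merged intervals are disjoint and non-bookended
            assert not got[r.start:r.end].any()
            got[r.start:r.end] = True
        assert np.array_equal(got, mask)

    def test_input_order_invariance(self):
        a = pc([("chr1", 10, 30), ("chr1", 100, 130)])
        b = pc([("chr1", 25, 60)])
        u1 = ch.merge_peak_union([a, b])
        u2 = ch.merge_peak_union([b, a])
        assert u1.df[["chrom", "start", "end"]].equals(
            u2.df[["chrom", "start", "end"]]
        )


class TestQuantify:
    def test_uniform_coverage_gives_constant_density(self):
        cov = {"s": {"chr1": np.full(1000, 3.5)}}
        peaks = pc([("chr1", 400, 600)], summits=[500])
        tm = ch.quantify_windows(peaks, cov, half_width=100)
        assert tm.values["s"].iloc[0] == pytest.approx(3.5)

    def test_cpm_scale_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.random(2000) * 5
        peaks = pc([("chr1", 400, 600), ("chr1", 1200, 1300)],
                   summits=[500, 1250])
        tm1 = ch.quantify_windows(peaks, {"s": {"chr1": base}}).to_cpm()
        tm2 = ch.quantify_windows(peaks, {"s": {"chr1": 2 * base}}).to_cpm()
        assert np.allclose(tm1.values, tm2.values)

    def test_synthetic_intensities_recovered(self, landscape):
        pcs = [ch.PeakCollection(df) for df in landscape.peak_sets.values()]
        union = ch.merge_peak_union(pcs)
        tm = ch.quantify_windows(union, landscape.coverage)
        # union summits coincide with input peak summits: raw densities
        # must equal the configured intensity matrix exactly
        by_summit = {
            int(r.summit): r.name for r in union.df.itertuples()
        }
        orig = pd.concat(landscape.peak_sets.values(), ignore_index=True)
        for r in orig.itertuples():
            uname = by_summit[int(r.summit)]
            for s in landscape.coverage:
                assert tm.values.loc[uname, s] == pytest.approx(
                    landscape.intensity.loc[r.name, s]
                )

    def test_additivity_raw(self):
        rng = np.random.default_rng(3)
        a = rng.random(1000)
        b = rng.random(1000)
        peaks = pc([("chr1", 300, 500)], summits=[400])
        qa = ch.quantify_windows(peaks, {"s": {"chr1": a}}).values
        qb = ch.quantify_windows(peaks, {"s": {"chr1": b}}).values
        qab = ch.quantify_windows(peaks, {"s": {"chr1": a + b}}).values
        assert np.allclose(qa + qb, qab)


class TestDifferentialSites:
    def make_tm(self, a_vals, b_vals):
        n = len(a_vals)
        peaks = pc(
            [("chr1", 1000 * i, 1000 * i + 200) for i in range(n)],
            summits=[1000 * i + 100 for i in range(n)],
        )
        vals = pd.DataFrame(
            {"A": a_vals, "B": b_vals},
            index=pd.Index(peaks.df["name"], name="peak"),
        )
        return ch.TagMatrix(vals, state="log2CPM", half_width=200,
                            totals=pd.Series({"A": 1e6, "B": 1e6}), peaks=peaks)

    def test_identical_samples_empty(self):
        tm = self.make_tm([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        a, b = ch.differential_sites(tm, "A", "B")
        assert len(a) == 0 and len(b) == 0

    def test_antisymmetric(self):
        tm = self.make_tm([5.0, 1.0, 3.0], [1.0, 5.0, 3.0])
        a1, b1 = ch.differential_sites(tm, "A", "B")
        a2, b2 = ch.differential_sites(tm, "B", "A")
        assert a1.df["name"].tolist() == b2.df["name"].tolist()
        assert b1.df["name"].tolist() == a2.df["name"].tolist()

    def test_planted_folds_recovered(self, landscape):
        pcs = [ch.PeakCollection(df) for df in landscape.peak_sets.values()]
        union = ch.merge_peak_union(pcs)
        tm = ch.quantify_windows(union, landscape.coverage).to_log2cpm()
        a, b = ch.differential_sites(tm, "condA", "condB")
        # set A peaks are 3-fold up in condA, set B in condB
        assert len(a) == len(landscape.peak_sets["A"])
        assert len(b) == len(landscape.peak_sets["B"])

    def test_raw_state_rejected_and_unknown_sample(self):
        tm = self.make_tm([1.0], [1.0])
        object.__setattr__(tm, "state", "raw")
        with pytest.raises(ValueError, match="log2CPM"):
            ch.differential_sites(tm, "A", "B")
        tm2 = self.make_tm([1.0], [1.0])
        with pytest.raises(ValueError, match="unknown sample"):
            ch.differential_sites(tm2, "A", "C")


class TestRankedDensity:
    def test_constant_coverage_all_bins_equal(self):
        cov = {"A": {"chr1": np.full(4000, 2.0)}, "B": {"chr1": np.full(4000, 2.0)}}
        peaks = pc([("chr1", 1900, 2100)], summits=[2000])
        mats = ch.ranked_density_matrix(cov, peaks, "A", "B",
                                        half_width=500, bin_size=10)
        assert np.allclose(mats["A"].to_numpy(), 2.0)

    def test_rows_ordered_by_fold_oracle(self):
        rng = np.random.default_rng(4)
        n = 20
        cov_a = {"chr1": np.zeros(40000)}
        cov_b = {"chr1": np.zeros(40000)}
        folds = []
        for i in range(n):
            c = 2000 * i + 1000
            va, vb = rng.uniform(1, 10), rng.uniform(1, 10)
            cov_a["chr1"][c - 500:c + 500] = va
            cov_b["chr1"][c - 500:c + 500] = vb
            folds.append(va / vb)
        peaks = pc([("chr1", 2000 * i + 900, 2000 * i + 1100) for i in range(n)],
                   summits=[2000 * i + 1000 for i in range(n)])
        mats = ch.ranked_density_matrix(
            {"A": cov_a, "B": cov_b}, peaks, "A", "B",
            half_width=500, bin_size=10,
        )
        expected = peaks.df["name"].to_numpy()[np.argsort(-np.array(folds),
                                                          kind="stable")]
        assert list(mats["A"].index) == list(expected)
        assert list(mats["B"].index) == list(expected)

    def test_bad_bin_errors(self):
        peaks = pc([("chr1", 0, 10)])
        with pytest.raises(ValueError, match="divide"):
            ch.ranked_density_matrix({"A": {}, "B": {}}, peaks, "A", "B",
                                     half_width=500, bin_size=7)


class TestAverageProfile:
    def cov_with_peak(self, height, n=4000, center=2000, width=100):
        arr = np.zeros(n)
        arr[center - width:center + width] = height
        return {"chr1": arr}

    def test_identical_samples_factor_one(self):
        covs = {"A": self.cov_with_peak(4.0), "B": self.cov_with_peak(4.0)}
        sites = pc([("chr1", 1900, 2100)], summits=[2000])
        _, factors = ch.normalized_average_profile(covs, sites, half_width=500)
        assert np.allclose(factors, 1.0)

    def test_doubled_sample_factor_ratio(self):
        covs = {"A": self.cov_with_peak(3.0), "B": self.cov_with_peak(6.0)}
        sites = pc([("chr1", 1900, 2100)], summits=[2000])
        profiles, factors = ch.normalized_average_profile(covs, sites,
                                                          half_width=500)
        assert factors["A"] / factors["B"] == pytest.approx(2.0)
        assert np.allclose(profiles["A"]["scaled"], profiles["B"]["scaled"])

    def test_fold_change_heatmap_matches_config(self, landscape):
        sets = {
            name: ch.PeakCollection(df)
            for name, df in landscape.peak_sets.items()
        }
        fc = ch.profile_fold_changes(landscape.coverage, sets, "condA", "condB",
                                     half_width=200, bin_size=10)
        assert fc["A"] == pytest.approx(np.log2(12.0 / 4.0))
        assert fc["B"] == pytest.approx(np.log2(4.0 / 12.0))

    def test_empty_sites_errors(self):
        empty = ch.PeakCollection(
            pd.DataFrame(columns=["chrom", "start", "end"]).astype(
                {"chrom": str, "start": int, "end": int}
            )
        )
        with pytest.raises(ValueError, match="empty"):
            ch.normalized_average_profile({"A": {}}, empty)


class TestBindingCorrelation:
    def make_tm(self, values):
        vals = pd.DataFrame(values)
        peaks = pc([("chr1", 100 * i, 100 * i + 50) for i in range(len(vals))])
        vals.index = pd.Index(peaks.df["name"])
        return ch.TagMatrix(vals, state="raw", half_width=200,
                            totals=pd.Series(dtype=float), peaks=peaks)

    def test_duplicated_sample_correlates_one(self):
        rng = np.random.default_rng(5)
        x = rng.random(30)
        corr, _ = ch.binding_correlation(self.make_tm({"A": x, "B": x.copy(),
                                                       "C": rng.random(30)}))
        assert corr.loc["A", "B"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(40), rng.random(40)
        c1, _ = ch.binding_correlation(self.make_tm({"A": x, "B": y}))
        c2, _ = ch.binding_correlation(self.make_tm({"A": np.exp(3 * x), "B": y}))
        assert c1.loc["A", "B"] == pytest.approx(c2.loc["A", "B"])

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        vals = {f"s{i}": rng.random(100) for i in range(5)}
        corr, _ = ch.binding_correlation(self.make_tm(vals))
        for a in vals:
            for b in vals:
                ra, rb = rankdata(vals[a]), rankdata(vals[b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_constant_sample_reported_missing(self):
        rng = np.random.default_rng(8)
        corr, order = ch.binding_correlation(
            self.make_tm({"A": rng.random(10), "B": np.full(10, 2.0),
                          "C": rng.random(10)})
        )
        assert np.isnan(corr.loc["A", "B"])
        assert "B" in order  # still listed, at the end


class TestAssignPeaksToGenes:
    tss = pd.DataFrame(
        {
            "gene": ["alpha", "beta", "gamma"],
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [1000, 5000, 300],
        }
    )

    def test_hic_overrides_nearest_tss(self):
        peaks = pc([("chr1", 900, 1100)], summits=[1000])  # alpha TSS inside
        hic = pd.DataFrame(
            {"chrom": ["chr1"], "start": [900], "end": [1100], "gene": ["beta"]}
        )
        out = ch.assign_peaks_to_genes(peaks, self.tss, hic)
        assert out["gene"].tolist() == ["beta"]
        assert out["source"].tolist() == ["hic"]

    def test_empty_hic_matches_bruteforce_nearest(self):
        rng = np.random.default_rng(9)
        summits = rng.integers(0, 8000, size=50)
        peaks = pc([("chr1", s, s + 10) for s in summits],
                   summits=list(summits))
        out = ch.assign_peaks_to_genes(peaks, self.tss, None)
        tss_chr1 = self.tss[self.tss.chrom == "chr1"]
        for row, summit in zip(out.itertuples(),
                               peaks.df["summit"]):
            dists = (tss_chr1["tss"] - summit).abs()
            best = dists.min()
            winners = sorted(tss_chr1.loc[dists == best, "gene"])
            assert row.gene == winners[0]

    def test_equidistant_tie_lexicographic(self):
        peaks = pc([("chr1", 2990, 3010)], summits=[3000])  # 2000 from both
        out = ch.assign_peaks_to_genes(peaks, self.tss, None)
        assert out["gene"].tolist() == ["alpha"]

    def test_unknown_chromosome_flagged(self):
        peaks = pc([("chrX", 10, 30)])
        out = ch.assign_peaks_to_genes(peaks, self.tss, None)
        assert out["source"].tolist() == ["unassigned"]


class TestBedgraphIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        arr = np.round(rng.random(500) * 4)
        path = tmp_path / "c.bedGraph"
        ch.write_bedgraph({"chr1": arr}, path)
        back = ch.read_bedgraph(path, chrom_sizes={"chr1": 500})
        assert np.allclose(back["chr1"], arr)

    def test_window_reaggregation_equals_intensity(self, landscape, tmp_path):
        # serialize + reload one sample, then re-check window means
        path = tmp_path / "condA.bedGraph"
        ch.write_bedgraph(landscape.coverage["condA"], path)
        cov = ch.read_bedgraph(path, chrom_sizes={"chr1": 140_000})
        union = ch.merge_peak_union(
            [ch.PeakCollection(df) for df in landscape.peak_sets.values()]
        )
        tm = ch.quantify_windows(union, {"condA": cov})
        assert np.allclose(
            np.sort(tm.values["condA"].to_numpy()),
            np.sort(landscape.intensity["condA"].to_numpy()),
        )
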