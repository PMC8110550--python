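import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caldera.analysis import (CompartmentPanel, ab_index_boundaries,
                              boundary_overlap, classify_boundary_level,
                              cluster_samples, compartment_entropy, delta_mu,
                              entropy_null, interdomain_contact_shift,
                              marker_enrichment, min_sufficient_compartments,
                              region_state_enrichment)
from caldera.hierarchy import LABELS_8
from caldera.segmentation import DomainSegmentation
from caldera.simulate import (SyntheticSpec, planted_hierarchy,
                              simulate_contact_map, simulate_panel,
                              simulate_track)


def make_panel(label_matrix):
    lab = pd.DataFrame(np.asarray(label_matrix, dtype=object))
    bins = pd.DataFrame({"chrom": "chr1",
                         "start": np.arange(len(lab)) * 40_000,
                         "end": (np.arange(len(lab)) + 1) * 40_000})
    return CompartmentPanel(bins=bins, labels=lab)


class TestEntropy:
    def test_constant_assignment_zero(self):
        p = make_panel([["A.1.1"] * 8, ["B.2.2"] * 8])
        s = compartment_entropy(p).entropy
        assert s[0] == 0.0 and s[1] == 0.0

    def test_uniform_eight_labels_one(self):
        p = make_panel([list(LABELS_8)])
        assert compartment_entropy(p).entropy[0] == pytest.approx(1.0)

    def test_two_labels_half_half_is_third(self):
        p = make_panel([["A.1.1"] * 4 + ["B.2.2"] * 4])
        assert compartment_entropy(p).entropy[0] == pytest.approx(1 / 3)

    def test_entropy_bounds_and_relabel_invariance(self):
        rng = np.random.default_rng(0)
        lab = rng.choice(LABELS_8, size=(50, 10))
        s1 = compartment_entropy(make_panel(lab)).entropy
        assert np.all((s1 >= 0) & (s1 <= 1 + 1e-12))
        perm = dict(zip(LABELS_8, np.roll(LABELS_8, 3)))
        s2 = compartment_entropy(
            make_panel(np.vectorize(perm.get)(lab))).entropy
        assert np.allclose(s1, s2)

    def test_missing_labels_excluded(self):
        p = make_panel([["A.1.1", None, "A.1.1", None]])
        prof = compartment_entropy(p)
        assert prof.entropy[0] == 0.0 and prof.n_samples[0] == 2

    def test_null_preserves_label_counts_and_is_deterministic(self):
        rng = np.random.default_rng(1)
        lab = rng.choice(LABELS_8[:4], size=(30, 6))
        p = make_panel(lab)
        a = entropy_null(p, n_perm=5, seed=9)
        b = entropy_null(p, n_perm=5, seed=9)
        assert np.array_equal(a, b)

    def test_null_mean_matches_multinomial_simulation(self):
        # every sample uses all 8 labels equally: the permutation null equals
        # i.i.d. multinomial draws; compare to a direct simulation oracle
        n_bins, n_samples = 64, 8
        lab = np.array([list(np.repeat(LABELS_8, n_bins // 8))
                        for _ in range(n_samples)]).T
        p = make_panel(lab)
        null = entropy_null(p, n_perm=200, seed=0)
        rng = np.random.default_rng(42)
        sim = []
        for _ in range(4000):
            draw = rng.integers(0, 8, n_samples)
            _, counts = np.unique(draw, return_counts=True)
            q = counts / n_samples
            sim.append(-(q * np.log(q)).sum() / np.log(8))
        assert null.mean() == pytest.approx(np.mean(sim), abs=0.02)


class TestBoundaryClassification:
    @pytest.mark.parametrize("a,b,expect", [
        ("A.1.1", "B.2.2", 1),
        ("A.1.1", "A.2.2", 2),
        ("A.1.1", "A.1.2", 3),
        ("A.1.1", "A.1.1", "gt3"),
    ])
    def test_first_differing_digit(self, a, b, expect):
        assert classify_boundary_level(a, b) == expect

    def test_nested_override_and_symmetry(self):
        assert classify_boundary_level("A.1.1", "A.1.1", is_nested=True) == \
            "nested"
        for a in LABELS_8:
            for b in LABELS_8:
                assert classify_boundary_level(a, b) == \
                    classify_boundary_level(b, a)

    def test_missing_label(self):
        assert classify_boundary_level(None, "A.1.1") == "unclassified"


class TestBoundaryOverlap:
    def test_identical_sets(self):
        frac, pairs = boundary_overlap([1e5, 5e5], [1e5, 5e5], 4e4)
        assert frac == 1.0 and len(pairs) == 2

    def test_exactly_max_dist_is_not_matched(self):
        frac, _ = boundary_overlap([100_000], [140_000], 40_000)
        assert frac == 0.0

    def test_partial_match(self):
        frac, pairs = boundary_overlap([100_000, 500_000],
                                       [139_000, 900_000], 40_000)
        assert frac == 0.5
        assert pairs == [(100_000.0, 139_000.0)]

    def test_empty_input_undefined(self):
        frac, _ = boundary_overlap([], [1.0], 10)
        assert frac is None

    def test_no_reuse_of_matches(self):
        frac, pairs = boundary_overlap([0, 10], [5], 100)
        assert frac == 0.5 and len(pairs) == 1


class TestABIndex:
    def oe_with_signs(self, signs):
        """Build an O/E matrix whose A-B index has the requested signs."""
        n = len(signs)
        ab = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        vals = np.ones((n, n))
        for i, s in enumerate(signs):
            vals[i, ab == "A"] = 1.0 + (0.5 if s > 0 else -0.5)
            vals[i, ab == "B"] = 1.0 - (0.5 if s > 0 else -0.5)
        return vals, ab

    def test_simple_switch(self):
        vals, ab = self.oe_with_signs([+1, +1, -1, -1])
        assert ab_index_boundaries(vals, ab).tolist() == [2]

    def test_single_bin_run_is_noise(self):
        vals, ab = self.oe_with_signs([+1, +1, -1, +1, +1])
        assert ab_index_boundaries(vals, ab).tolist() == []

    def test_two_switches(self):
        vals, ab = self.oe_with_signs([+1, -1, -1, +1, +1])
        assert ab_index_boundaries(vals, ab).tolist() == [1, 3]

    def test_all_one_sign(self):
        vals, ab = self.oe_with_signs([+1, +1, +1, +1])
        assert ab_index_boundaries(vals, ab).size == 0


class TestEnrichment:
    def seg_labels(self):
        seg = DomainSegmentation([(0, 4), (4, 8), (8, 12), (12, 16)],
                                 "chr1", 40_000)
        labels = ["A.1.1", "B.2.2", "A.1.1", "B.1.1"]
        return seg, labels

    def test_constant_track_zero_enrichment(self):
        seg, labels = self.seg_labels()
        enr = marker_enrichment(np.ones(16), seg, labels)
        for lab in ("A.1.1", "B.2.2", "B.1.1"):
            assert enr[lab] == pytest.approx(0.0)
        assert np.isnan(enr["A.2.2"])

    def test_doubled_label_gives_log2_one(self):
        seg, labels = self.seg_labels()
        track = np.ones(16)
        track[0:4] = 2.0
        track[8:12] = 2.0
        enr = marker_enrichment(track, seg, labels)
        # overall median across domain means (2,1,2,1) is 1.5
        assert enr["A.1.1"] == pytest.approx(np.log2(2 / 1.5))

    def test_region_least_active_and_mean_rank(self):
        seg = DomainSegmentation([(0, 4), (4, 8)], "chr1", 40_000)
        labels = ["A.1.1", "B.1.2"]
        ranks = [1.0, 0.4]
        regions = pd.DataFrame([("chr1", 100_000, 200_000, "Tss")],
                               columns=["chrom", "start", "end", "state"])
        # spans both domains: least active label, mean rank
        out = region_state_enrichment(regions, seg, labels, ranks)
        assert out.loc["Tss", "B.1.2"] > 0
        assert out.loc["Tss", "A.1.1"] == 0

    def test_proportional_regions_ratio_one(self):
        seg = DomainSegmentation([(0, 4), (4, 8)], "chr1", 40_000)
        labels = ["A.1.1", "B.2.2"]
        ranks = [1.0, 0.1]
        rows = []
        for s in range(0, 8):
            rows.append(("chr1", s * 40_000 + 1000, s * 40_000 + 2000, "X"))
        regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        out = region_state_enrichment(regions, seg, labels, ranks)
        assert out.loc["X", "A.1.1"] == pytest.approx(1.0)
        assert out.loc["X", "B.2.2"] == pytest.approx(1.0)

    def test_single_label_ratio_inverse_frequency(self):
        seg = DomainSegmentation([(0, 4), (4, 8)], "chr1", 40_000)
        labels = ["A.1.1", "B.2.2"]
        rows = [("chr1", 1000, 2000, "X"), ("chr1", 50_000, 60_000, "X")]
        regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        regions = regions.iloc[[0]]
        out = region_state_enrichment(regions, seg, labels, [1.0, 0.1])
        assert out.loc["X", "A.1.1"] == pytest.approx(1 / 0.5)


class TestDeltaMuAndCompartmentCount:
    def test_bisection_matches_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 30)
        y = rng.normal(3, 2, 25)
        d = delta_mu(x, y, alpha=0.001, tol=1e-8)
        vx, vy = x.var(ddof=1) / 30, y.var(ddof=1) / 25
        df = (vx + vy) ** 2 / (vx ** 2 / 29 + vy ** 2 / 24)
        closed = x.mean() - y.mean() - \
            stats.t.ppf(1 - 0.001, df) * np.sqrt(vx + vy)
        assert d == pytest.approx(closed, abs=1e-6)

    @staticmethod
    def planted_tracks(effect, noise_sd=0.05, n_chrom=5):
        tracks, hiers = {}, {}
        for c in range(n_chrom):
            spec = SyntheticSpec(n_bins=480, n_domains=40, seed=100 + c)
            _, gt = simulate_contact_map(spec)
            tr = simulate_track(gt, effect=effect, noise_sd=noise_sd,
                                seed=200 + c, log_scale=True)
            tracks[f"chr{c + 1}"] = np.array(
                [tr[s:e].mean() for s, e in gt.domains])
            hiers[f"chr{c + 1}"] = planted_hierarchy(gt)
        return tracks, hiers

    def test_planted_eight_class_track_recovers_eight(self):
        tracks, hiers = self.planted_tracks(effect=8.0)
        assert min_sufficient_compartments(tracks, hiers) >= 8

    def test_constant_track_returns_one(self):
        tracks, hiers = self.planted_tracks(effect=8.0)
        const = {c: np.ones_like(v) for c, v in tracks.items()}
        assert min_sufficient_compartments(const, hiers) == 1

    def test_monotone_in_effect_size(self):
        results = []
        for effect in [0.0, 2.0, 8.0]:
            tracks, hiers = self.planted_tracks(effect=effect)
            results.append(min_sufficient_compartments(tracks, hiers))
        assert all(a <= b for a, b in zip(results, results[1:]))


class TestClusterSamples:
    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(0)
        base = rng.choice(LABELS_8, 40)
        other = base.copy()
        other[:20] = np.roll(LABELS_8, 1)[
            [LABELS_8.index(l) for l in other[:20]]]
        p = make_panel(np.column_stack([base, base, other]))
        Z, flat, D = cluster_samples(p)
        assert D[0, 1] == 0.0
        assert Z[0, 0] == 0 and Z[0, 1] == 1  # identical pair merges first

    def test_fully_relabeled_distance_one(self):
        base = np.array(["A.1.1"] * 30)
        other = np.array(["B.2.2"] * 30)
        p = make_panel(np.column_stack([base, other]))
        _, _, D = cluster_samples(p)
        assert D[0, 1] == 1.0

    def test_forced_linkage_order(self):
        # pairwise distances 0.1 / 0.4 / 0.4: the close pair merges first
        a = np.array(["A.1.1"] * 10)
        b = a.copy(); b[:1] = "A.1.2"
        c = a.copy(); c[:4] = "B.2.2"
        p = make_panel(np.column_stack([a, b, c]))
        Z, _, D = cluster_samples(p)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_no_common_bins_error(self):
        lab = np.array([["A.1.1", None], [None, "B.2.2"]], dtype=object)
        with pytest.raises(ValueError, match="share no covered bins"):
            cluster_samples(make_panel(lab))


class TestInterdomainShift:
    def test_identical_conditions_no_shift(self):
        rng = np.random.default_rng(0)
        oe = 1 + rng.normal(0, 0.1, (40, 40))
        stable = {"A.1.1": [(20, 30)], "B.2.2": [(30, 40)]}
        out = interdomain_contact_shift(oe, oe, (0, 10), stable)
        for lab in out:
            assert out[lab]["median_a"] == out[lab]["median_b"]

    def test_doubled_contacts_double_medians(self):
        rng = np.random.default_rng(1)
        oe_a = 1 + rng.random((40, 40))
        oe_b = oe_a.copy()
        oe_b[0:10, 20:30] *= 2
        oe_b[20:30, 0:10] *= 2
        out = interdomain_contact_shift(oe_a, oe_b, (0, 10),
                                        {"A.1.1": [(20, 30)]})
        assert out["A.1.1"]["median_b"] == \
            pytest.approx(2 * out["A.1.1"]["median_a"])

    def test_constant_matrices_give_ones(self):
        oe = np.ones((20, 20))
        out = interdomain_contact_shift(oe, oe, (0, 5), {"X": [(10, 15)]})
        assert out["X"]["median_a"] == 1.0


def test_observed_entropy_below_null_with_conserved_extremes():
    """Panels with conserved extremes and labile intermediates have entropy
    significantly below the permutation null, and intermediate-class bins
    have higher entropy than the extreme classes."""
    spec = SyntheticSpec(n_bins=400, seed=5)
    rates = {l: (0.1 if l in ("A.1.1", "B.2.2") else 0.8) for l in LABELS_8}
    panel, (gt, _) = simulate_panel(spec, n_samples=20,
                                    reposition_rate_by_class=rates, seed=7)
    prof = compartment_entropy(panel)
    obs = np.nanmean(prof.entropy)
    null_means = entropy_null(panel, n_perm=200, seed=3, per_permutation=True)
    p_emp = (np.sum(null_means <= obs) + 1) / (len(null_means) + 1)
    assert p_emp < 0.01
    extreme = np.isin(gt.bin_labels, ["A.1.1", "B.2.2"])
    assert np.nanmedian(prof.entropy[~extreme]) > \
        np.nanmedian(prof.entropy[extreme])
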