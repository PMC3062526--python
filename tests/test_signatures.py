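"""Signature averaging, module clustering, cloud plots."""

import numpy as np
import pytest

from pph.quantification import INTERLACED_TIMES_S
from pph.randomization import build_null_bands
from pph.signatures import (RecruitmentSignature, average_signature,
                            cloud_plot, cluster_signatures)
from pph.synthetic import family_profile

TIMES = INTERLACED_TIMES_S


def sig(name, trace):
    return RecruitmentSignature(protein=name, trace=np.asarray(trace, float))


def brute_force_average_linkage(dist: np.ndarray):
    """Independent oracle: textbook agglomerative average linkage on a
    full distance matrix.  Returns the merge list [(members_a,
    members_b, height), ...] in merge order."""
    clusters = {i: [i] for i in range(len(dist))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a]), sorted(clusters[b]), d))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


class TestAverageSignature:
    def test_single_trace_is_itself(self):
        tr = np.sin(TIMES / 10)
        out = average_signature(tr[None, :], "x")
        assert np.allclose(out.trace, tr)
        assert out.n_events == 1

    def test_mirrored_traces_average_to_zero(self):
        tr = np.sin(TIMES / 7)
        out = average_signature(np.stack([tr, -tr]), "x")
        assert np.allclose(out.trace, 0.0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            average_signature(np.empty((0, 80)), "x")

    def test_planted_peak_time_recovered_from_many_noisy_traces(self):
        """1,000 dynamin-like traces with peak at -3 s average to a
        signature peaking within +/-2 s of -3 s."""
        rng = np.random.default_rng(6)
        traces = np.stack([
            10.0 * family_profile(TIMES + rng.uniform(0, 2), "dynamin-like")
            + rng.normal(0, 3.0, 80)
            for _ in range(1000)])
        out = average_signature(traces, "dyn")
        t_peak = TIMES[np.argmax(out.trace)]
        assert abs(t_peak - (-3.0)) <= 2.0

    def test_normalized_via_bands(self):
        rng = np.random.default_rng(7)
        bands = build_null_bands(rng.normal(0, 1, size=(100, 80)))
        out = average_signature(np.zeros((3, 80)), "x", bands=bands)
        assert np.nanmax(np.abs(out.trace)) < 1.0  # zero avg sits in the null


class TestClusterSignatures:
    def test_identical_pair_single_module_distance_zero(self):
        tr = np.sin(TIMES / 9)
        out = cluster_signatures([sig("a", tr), sig("b", tr.copy())])
        assert out.n_modules == 1
        assert out.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_distance_two_two_modules(self):
        tr = np.sin(TIMES / 9)
        out = cluster_signatures([sig("a", tr), sig("b", -tr)])
        assert out.n_modules == 2
        assert out.linkage_matrix[0, 2] == pytest.approx(2.0)

    def test_constant_signature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cluster_signatures([sig("a", np.ones(80)),
                                sig("b", np.sin(TIMES))])

    def test_merge_order_and_heights_match_hand_executed_linkage(self):
        """Four curves with distinct pairwise correlations: scipy's tree
        must equal a from-scratch average-linkage trace."""
        rng = np.random.default_rng(8)
        base = np.sin(TIMES / 8)
        curves = [base,
                  base + rng.normal(0, 0.1, 80),
                  np.cos(TIMES / 8) + rng.normal(0, 0.05, 80),
                  rng.normal(0, 1.0, 80)]
        sigs = [sig(f"p{i}", c) for i, c in enumerate(curves)]
        # independent distance matrix from plain Pearson correlation
        dist = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                dist[i, j] = 1.0 - np.corrcoef(curves[i], curves[j])[0, 1]
        oracle = brute_force_average_linkage(dist)
        out = cluster_signatures(sigs)
        Z = out.linkage_matrix
        # map scipy cluster ids to member sets
        members = {i: [i] for i in range(4)}
        for m, (ia, ib, height, _) in enumerate(Z):
            got_a = sorted(members[int(ia)])
            got_b = sorted(members[int(ib)])
            exp_a, exp_b, exp_h = oracle[m]
            assert {tuple(got_a), tuple(got_b)} == {tuple(exp_a), tuple(exp_b)}
            assert height == pytest.approx(exp_h, rel=1e-9)
            members[4 + m] = got_a + got_b

    def test_planted_three_module_structure_recovered_exactly(self):
        """3 signature families x 5 noisy replicates -> 3 modules at cut
        0.2 with Rand index 1.0 against the planted labels."""
        rng = np.random.default_rng(9)
        shapes = [family_profile(TIMES, f)
                  for f in ("dynamin-like", "clathrin-like", "gak-like")]
        sigs, labels = [], []
        for fam, shape in enumerate(shapes):
            for rep in range(5):
                noisy = shape + rng.normal(0, 0.04, 80)
                assert np.corrcoef(noisy, shape)[0, 1] >= 0.9
                sigs.append(sig(f"f{fam}r{rep}", noisy))
                labels.append(fam)
        out = cluster_signatures(sigs, cut_distance=0.2)
        assert out.n_modules == 3
        got = [out.modules[s.protein] for s in sigs]
        # Rand index against planted labels
        agree = sum((labels[i] == labels[j]) == (got[i] == got[j])
                    for i in range(15) for j in range(i + 1, 15))
        assert agree == 15 * 14 // 2  # Rand index exactly 1.0
        assert 0 < out.cophenetic_r <= 1.0

    def test_invariance_to_input_order_and_affine_rescaling(self):
        rng = np.random.default_rng(10)
        shapes = [family_profile(TIMES, f)
                  for f in ("dynamin-like", "clathrin-like", "gak-like")]
        sigs = [sig(f"s{i}", s + rng.normal(0, 0.03, 80))
                for i, s in enumerate(shapes * 2)]
        ref = cluster_signatures(sigs)
        perm = [sigs[i] for i in rng.permutation(len(sigs))]
        scaled = [sig(s.protein, 3.7 * s.trace + 11.0) for s in perm]
        out = cluster_signatures(scaled)
        for a in sigs:
            for b in sigs:
                same_ref = ref.modules[a.protein] == ref.modules[b.protein]
                same_out = out.modules[a.protein] == out.modules[b.protein]
                assert same_ref == same_out


class TestCloudPlot:
    def test_single_flat_trace_is_a_horizontal_line(self):
        img = cloud_plot(np.full((1, 80), 5.0))
        occupied = np.argwhere(img > 0)
        assert len(occupied) == 80                      # one bin per column
        assert len(set(occupied[:, 0])) == 1            # single row
        assert np.allclose(img[img > 0], np.log1p(1.0))

    def test_identical_traces_share_support_with_counts_times_n(self):
        tr = np.sin(TIMES / 11)[None, :]
        one = cloud_plot(tr)
        five = cloud_plot(np.repeat(tr, 5, axis=0))
        assert np.array_equal(one > 0, five > 0)
        assert np.allclose(np.expm1(five[five > 0]),
                           5 * np.expm1(one[one > 0]))

    def test_density_ridge_follows_planted_family_mean(self):
        rng = np.random.default_rng(11)
        shape = family_profile(TIMES, "dynamin-like")
        traces = np.stack([shape + rng.normal(0, 0.05, 80)
                           for _ in range(300)])
        img = cloud_plot(traces, n_value_bins=200)
        # the ridge (argmax per column) tracks the rasterized mean trace
        mean_processed = (traces - traces.min()) / (traces.max() - traces.min())
        mean_processed = (mean_processed
                          - mean_processed.mean(axis=1, keepdims=True)).mean(0)
        vmin = (traces - traces.min()) / (traces.max() - traces.min())
        # recompute bin of the family mean exactly as cloud_plot does
        norm = (traces - traces.min()) / (traces.max() - traces.min())
        norm = norm - norm.mean(axis=1, keepdims=True)
        lo, hi = norm.min(), norm.max()
        mean_rows = np.clip(((norm.mean(0) - lo) / (hi - lo) * 199).round(),
                            0, 199).astype(int)
        ridge = img.argmax(axis=0)
        assert np.median(np.abs(ridge - mean_rows)) <= 2.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cloud_plot(np.empty((0, 80)))


def test_restricted_window_clustering_is_stable():
    """Reclustering on the -44..+36 s window changes no module
    co-membership for well-separated signature families."""
    from pph.signatures import restricted_window_comparison

    rng = np.random.default_rng(12)
    sigs = []
    for fam_i, fam in enumerate(("dynamin-like", "clathrin-like",
                                 "gak-like")):
        for rep in range(4):
            sigs.append(sig(f"f{fam_i}r{rep}",
                            family_profile(TIMES, fam)
                            + rng.normal(0, 0.04, 80)))
    out = restricted_window_comparison(sigs, TIMES)
    assert out["n_pairings_changed"] <= 3
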