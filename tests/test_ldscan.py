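"""LD scan: EM haplotype frequencies, focal scan, nulls, windows."""

import numpy as np
import pytest

from assortscan.io_formats import MISSING, GenotypeMatrix, ValidationError, VariantSite
from assortscan.ldscan import (
    LDScanResult,
    _em_batch,
    _r2_from,
    distance_ld_profile,
    em_haplotype_freqs,
    empirical_null_threshold,
    focal_ld_scan,
    fraction_at_distance,
    haplotype_r2,
    sliding_window_r2,
)


def grid_oracle_r2(table, fine=1e-6):
    """Grid-search ML of the two-locus haplotype frequency (coarse-to-fine),
    independent of the EM implementation."""
    t = np.asarray(table, float)
    n = t.sum()
    twoN = 2 * n
    pA = (2 * t[2, :].sum() + t[1, :].sum()) / twoN
    pB = (2 * t[:, 2].sum() + t[:, 1].sum()) / twoN
    nAB0 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    nAb0 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    naB0 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    nab0 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    ndh = t[1, 1]
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)

    def ll(pAB):
        f = np.clip(np.stack([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB]),
                    1e-300, None)
        return (nAB0 * np.log(f[0]) + nAb0 * np.log(f[1])
                + naB0 * np.log(f[2]) + nab0 * np.log(f[3])
                + ndh * np.log(np.clip(f[0] * f[3] + f[1] * f[2], 1e-300, None)))

    g = np.linspace(lo, hi, 2001)
    best = g[np.argmax(ll(g))]
    step = (hi - lo) / 2000 if hi > lo else 0.0
    g2 = np.arange(max(lo, best - step), min(hi, best + step) + fine, fine)
    if len(g2):
        best = g2[np.argmax(ll(g2))]
    var = pA * (1 - pA) * pB * (1 - pB)
    return (best - pA * pB) ** 2 / var if var > 0 else float("nan")


class TestEmHaplotypeFreqs:
    def test_perfect_association(self):
        d = np.array([0, 0, 2, 2])
        hf = em_haplotype_freqs(d, d)
        assert hf.r2 == pytest.approx(1.0)
        assert hf.converged

    def test_balanced_independence(self):
        # 25 of each haplotype pair AB/AB, Ab/Ab, aB/aB, ab/ab collapses to
        # genotype counts with D = 0
        dosA = np.repeat([2, 2, 0, 0], 25)
        dosB = np.repeat([2, 0, 2, 0], 25)
        hf = em_haplotype_freqs(dosA, dosB)
        assert hf.D == pytest.approx(0.0, abs=1e-9)
        assert hf.r2 == pytest.approx(0.0, abs=1e-9)

    def test_double_het_table_matches_grid_oracle(self):
        # counts AABB=4, AaBb=4, aabb=4: phase of the double hets unknown
        dosA = np.repeat([2, 1, 0], 4)
        dosB = np.repeat([2, 1, 0], 4)
        t = np.zeros((3, 3))
        np.add.at(t, (dosA, dosB), 1)
        hf = em_haplotype_freqs(dosA, dosB)
        assert hf.r2 == pytest.approx(grid_oracle_r2(t), abs=1e-4)

    def test_monomorphic_flagged_not_raised(self):
        hf = em_haplotype_freqs(np.zeros(10, int), np.tile([0, 2], 5))
        assert np.isnan(hf.r2)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValidationError):
            em_haplotype_freqs(np.array([1]), np.array([1]))

    def test_matches_grid_oracle_on_random_tables(self, rng):
        """|r2_EM - r2_grid| < 1e-4 on several hundred random tables."""
        worst = 0.0
        for _ in range(300):
            t = rng.integers(0, 12, size=(3, 3)).astype(float)
            pA, pB, pAB, *_ = _em_batch(t)
            _, r2 = _r2_from(pA, pB, pAB)
            ref = grid_oracle_r2(t)
            if np.isnan(ref) or np.isnan(r2[0]):
                assert np.isnan(ref) == np.isnan(r2[0])
                continue
            worst = max(worst, abs(float(r2[0]) - ref))
        assert worst < 1e-4

    def test_label_swap_and_order_invariance(self, rng):
        dosA = rng.integers(0, 3, 40)
        dosB = rng.integers(0, 3, 40)
        base = em_haplotype_freqs(dosA, dosB).r2
        assert em_haplotype_freqs(2 - dosA, dosB).r2 == pytest.approx(base, abs=1e-9)
        assert em_haplotype_freqs(dosA, 2 - dosB).r2 == pytest.approx(base, abs=1e-9)
        perm = rng.permutation(40)
        assert em_haplotype_freqs(dosA[perm], dosB[perm]).r2 == pytest.approx(
            base, abs=1e-12)

    def test_em_exact_when_phase_unambiguous(self, rng):
        """Without double heterozygotes every haplotype is observable and
        the EM r2 equals the squared haplotype correlation to 1e-10."""
        for _ in range(20):
            hapA = rng.integers(0, 2, size=(80, 2))
            hapB = rng.integers(0, 2, size=(80, 2))
            keep = ~((hapA.sum(1) == 1) & (hapB.sum(1) == 1))
            hA, hB = hapA[keep], hapB[keep]
            if len(hA) < 2:
                continue
            truth = haplotype_r2(hA.ravel(), hB.ravel())
            est = em_haplotype_freqs(hA.sum(1), hB.sum(1)).r2
            if np.isnan(truth):
                assert np.isnan(est)
            else:
                assert est == pytest.approx(truth, abs=1e-10)

    def test_em_recovers_phased_truth_r2(self, small_sim):
        """With true haplotypes in hand, EM r2 from unphased dosages agrees
        with the squared haplotype correlation to sampling exactness."""
        res = small_sim
        males = res.male_indices
        h = res.haps[males]
        sig, pref = res.signal_idx, res.pref_idx
        true_r2 = haplotype_r2(h[:, :, sig].ravel(), h[:, :, pref].ravel())
        dos = res.dosage(males)
        est = em_haplotype_freqs(dos[:, sig], dos[:, pref]).r2
        # same sample, same haplotypes; EM only resolves double-het phase
        assert est == pytest.approx(true_r2, abs=0.02)


def _matrix_from_dosage(dos, chrom="Z", spacing=10):
    n, m = dos.shape
    sites = [VariantSite(chrom, 1 + j * spacing, "A", "T") for j in range(m)]
    return GenotypeMatrix(sites, [f"s{i}" for i in range(n)],
                          dos.astype(np.int8))


class TestFocalScan:
    def test_single_focal_equals_pairwise(self, rng):
        dos = rng.integers(0, 3, size=(40, 5))
        sites = ([VariantSite("aut1", 100, "A", "T")]
                 + [VariantSite("Z", 10 * (j + 1), "A", "T") for j in range(4)])
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(40)],
                            dos.astype(np.int8))
        scan = focal_ld_scan(gm, [("aut1", 100)], "Z")
        jf = gm.site_index("aut1", 100)
        for tj, tsite in enumerate(scan.target_sites):
            j = gm.site_index(tsite.chrom, tsite.pos)
            ref = em_haplotype_freqs(gm.dosage[:, jf], gm.dosage[:, j]).r2
            got = scan.max_r2[tj]
            assert (np.isnan(ref) and np.isnan(got)) or got == pytest.approx(ref)

    def test_duplicate_focal_idempotent(self, rng):
        dos = rng.integers(0, 3, size=(40, 4))
        sites = ([VariantSite("aut1", 100, "A", "T")]
                 + [VariantSite("Z", 10 * (j + 1), "A", "T") for j in range(3)])
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(40)],
                            dos.astype(np.int8))
        a = focal_ld_scan(gm, [("aut1", 100)], "Z")
        b = focal_ld_scan(gm, [("aut1", 100), ("aut1", 100)], "Z")
        assert np.allclose(a.max_r2, b.max_r2, equal_nan=True)

    def test_all_missing_focal_skipped(self, rng, caplog):
        dos = rng.integers(0, 3, size=(30, 3))
        dos[:, 0] = MISSING
        sites = [VariantSite("aut1", 100, "A", "T"),
                 VariantSite("aut1", 5000, "A", "T"),
                 VariantSite("Z", 10, "A", "T")]
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(30)],
                            dos.astype(np.int8))
        scan = focal_ld_scan(gm, [("aut1", 100), ("aut1", 5000)], "Z")
        assert all(f is None or f.pos == 5000 for f in scan.argmax_focal)

    def test_flag_count_matches_threshold_rule(self, rng):
        dos = rng.integers(0, 3, size=(50, 10))
        sites = ([VariantSite("aut1", 100, "A", "T")]
                 + [VariantSite("Z", 10 * (j + 1), "A", "T") for j in range(9)])
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(50)],
                            dos.astype(np.int8))
        scan = focal_ld_scan(gm, [("aut1", 100)], "Z")
        scan.apply_threshold(0.05)
        expected = np.nansum(np.nan_to_num(scan.max_r2, nan=-1) > 0.05)
        assert scan.flags.sum() == expected

    def test_empty_focal_rejected(self, small_panel):
        _, _, gm = small_panel
        with pytest.raises(ValidationError):
            focal_ld_scan(gm, [], "Z")


class TestNullThreshold:
    def test_percentile_of_known_distribution(self):
        """Construct unlinked pairs whose r2 values are exactly 0 or 1 and
        check the interpolated percentile against a sort-based oracle."""
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(60, 1))
        # 11 perfect copies on different chromosomes -> all pair r2 = 1
        dos = np.repeat(base, 11, axis=1)
        sites = [VariantSite(f"c{j}", 100, "A", "T") for j in range(11)]
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(60)],
                            dos.astype(np.int8))
        thr, vals = empirical_null_threshold(
            gm, percentile=50.0, min_pairs=10, return_values=True)
        assert np.sort(vals)[len(vals) // 2] == pytest.approx(thr)
        assert thr == pytest.approx(1.0)

    def test_close_pairs_excluded_by_distance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=(80, 1))
        b = rng.integers(0, 3, size=(80, 1))
        # same chromosome: two perfectly correlated sites 100 bp apart
        # (excluded) and an unlinked site 2 Mb away (kept)
        dos = np.hstack([a, a, b])
        sites = [VariantSite("Z", 1000, "A", "T"),
                 VariantSite("Z", 1100, "A", "T"),
                 VariantSite("Z", 2_001_000, "A", "T")]
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(80)],
                            dos.astype(np.int8))
        thr, vals = empirical_null_threshold(
            gm, percentile=99.0, min_dist_bp=1_000_000, min_pairs=2,
            return_values=True)
        assert len(vals) == 2  # (s1,s3) and (s2,s3); the r2=1 pair dropped
        assert thr < 0.5

    def test_too_few_pairs_raises(self, small_panel):
        _, _, gm = small_panel
        with pytest.raises(ValidationError, match="qualifying"):
            empirical_null_threshold(gm, min_pairs=10**9)

    def test_invalid_percentile(self, small_panel):
        _, _, gm = small_panel
        with pytest.raises(ValidationError):
            empirical_null_threshold(gm, percentile=100.0)


class TestDistanceProfile:
    def test_adjacent_perfect_pair(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, size=(50, 1))
        dos = np.hstack([a, a])
        sites = [VariantSite("Z", 5000, "A", "T"),
                 VariantSite("Z", 5001, "A", "T")]
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(50)],
                            dos.astype(np.int8))
        with pytest.raises(ValidationError, match="longer"):
            distance_ld_profile(gm, "Z", region_len_bp=15_000, n_regions=1)
        prof = distance_ld_profile(gm, "Z", region_len_bp=2, n_regions=1)
        assert fraction_at_distance(prof, 1, 0.7) == pytest.approx(1.0)
        assert np.isnan(fraction_at_distance(prof, 7, 0.7))

    def test_decay_with_distance_on_block_structure(self):
        """Haplotype blocks with recombination: mean r2 falls with distance."""
        rng = np.random.default_rng(4)
        n, m = 200, 30
        pos = np.arange(1, m + 1)  # 1 bp apart, regions of 30 bp
        anc = rng.integers(0, 2, size=(2 * n, 1))
        haps = np.repeat(anc, m, axis=1)
        # sprinkle switch points so correlation decays along the region
        for h in range(2 * n):
            for sw in np.flatnonzero(rng.random(m) < 0.08):
                haps[h, sw:] = 1 - haps[h, sw:]
        dos = haps[:n] + haps[n:]
        sites = [VariantSite("Z", int(p), "A", "T") for p in pos]
        gm = GenotypeMatrix(sites, [f"s{i}" for i in range(n)],
                            dos.astype(np.int8))
        prof = distance_ld_profile(gm, "Z", region_len_bp=30, n_regions=1)
        prof = prof.dropna(subset=["r2"])
        near = prof[prof["distance"] <= 5]["r2"].mean()
        far = prof[prof["distance"] >= 20]["r2"].mean()
        assert near > far


class TestSlidingWindow:
    def _scan(self, positions, values, chrom="Z"):
        return LDScanResult(
            target_sites=[VariantSite(chrom, int(p), "A", "T")
                          for p in positions],
            max_r2=np.asarray(values, float),
            argmax_focal=[None] * len(positions),
            n_eff=np.zeros(len(positions), int),
        )

    def test_single_site_covering_windows(self):
        track = sliding_window_r2(self._scan([1500], [0.4]),
                                  window_bp=1000, step_bp=100)
        covered = track.dropna(subset=["mean_r2"])
        assert (covered["mean_r2"] == 0.4).all()
        assert ((covered["start"] <= 1500)
                & (1500 <= covered["end"])).all()

    def test_constant_track(self):
        pos = np.arange(1000, 3000, 37)
        track = sliding_window_r2(self._scan(pos, np.full(len(pos), 0.25)))
        assert np.allclose(track.dropna(subset=["mean_r2"])["mean_r2"], 0.25)

    def test_matches_brute_force(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 5000), 120, replace=False))
        vals = rng.random(120)
        vals[rng.random(120) < 0.15] = np.nan
        track = sliding_window_r2(self._scan(pos, vals),
                                  window_bp=1000, step_bp=100)
        for _, row in track.iloc[::7].iterrows():
            sel = (pos >= row["start"]) & (pos < row["start"] + 1000)
            sub = vals[sel]
            sub = sub[~np.isnan(sub)]
            if len(sub) == 0:
                assert np.isnan(row["mean_r2"])
            else:
                assert row["mean_r2"] == pytest.approx(sub.mean())
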