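"""Windowed statistics: estimator arithmetic, oracles, and classification."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from divflow.windows import (
    classify_early,
    dxy,
    fst_wc,
    fst_wc_sitewise,
    mann_whitney,
    rare_shared_fraction,
    scan,
    tajimas_d,
    window_pi,
)

from conftest import build_table


def _single_pop_table(allele_rows, pops=None):
    """Sites x haploid-allele matrix (one pop of diploids) -> VariantTable."""
    arr = np.asarray(allele_rows, dtype=np.int8)
    S, H = arr.shape
    gt = arr.reshape(S, H // 2, 2)
    return build_table(gt, pops=pops or ["sp1"] * (H // 2))


class TestPi:
    def test_singleton_site_value(self):
        """One singleton among 12 alleles in a 30 kb window."""
        vt = _single_pop_table([[1] + [0] * 11])
        val = window_pi(vt, "sp1", 30_000, "window_length").iloc[0]
        expected = (2 * 1 * 11 / (12 * 11)) / 30_000
        assert val == pytest.approx(expected)

    def test_monomorphic_window_is_zero(self):
        vt = _single_pop_table([[0] * 12])
        assert window_pi(vt, "sp1").iloc[0] == 0.0

    def test_per_site_denominator(self):
        vt = _single_pop_table([[1] * 6 + [0] * 6, [1] + [0] * 11])
        per_site = window_pi(vt, "sp1", denominator="genotyped_sites").iloc[0]
        h1 = 2 * 6 * 6 / (12 * 11)
        h2 = 2 * 1 * 11 / (12 * 11)
        assert per_site == pytest.approx((h1 + h2) / 2)

    def test_empty_window_missing(self):
        vt = _single_pop_table([[1] + [0] * 11], )
        vt.pos[0] = 65_000  # third window; first two have no sites
        series = window_pi(vt, "sp1")
        assert np.isnan(series.iloc[0]) and np.isnan(series.iloc[1])
        assert not np.isnan(series.iloc[2])


class TestTajimasD:
    def test_balanced_frequencies_positive(self):
        rows = [[1] * 6 + [0] * 6] * 8
        vt = _single_pop_table(rows)
        assert tajimas_d(vt, "sp1").iloc[0] > 0

    def test_singletons_negative(self):
        rows = [[1] + [0] * 11] * 8
        vt = _single_pop_table(rows)
        assert tajimas_d(vt, "sp1").iloc[0] < 0

    def test_no_segregating_sites_missing(self):
        vt = _single_pop_table([[0] * 12])
        assert np.isnan(tajimas_d(vt, "sp1").iloc[0])

    def test_small_sample_missing(self):
        vt = _single_pop_table([[1, 0]], pops=["sp1"])
        assert np.isnan(tajimas_d(vt, "sp1").iloc[0])

    def test_matches_independent_implementation(self):
        """Cross-check against dendropy's implementation on one window."""
        popgenstat = pytest.importorskip("dendropy.calculate.popgenstat")
        import dendropy

        rng = np.random.default_rng(11)
        rows = (rng.random((40, 12)) < rng.uniform(0.1, 0.9, (40, 1)))
        rows = rows.astype(np.int8)
        seg = (rows.sum(1) > 0) & (rows.sum(1) < 12)
        rows = rows[seg]
        vt = _single_pop_table(rows)
        ours = tajimas_d(vt, "sp1").iloc[0]

        seqs = ["".join("AT"[a] for a in rows[:, h]) for h in range(12)]
        dna = dendropy.DnaCharacterMatrix.get(
            data="".join(f">h{i}\n{s}\n" for i, s in enumerate(seqs)),
            schema="fasta",
        )
        theirs = popgenstat.tajimas_d(dna)
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestDxy:
    def test_fixed_difference_site(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, :6] = 1  # sp1 all alt, sp2 all ref
        vt = build_table(gt)
        assert dxy(vt).iloc[0] == pytest.approx(1.0)

    def test_shared_polymorphism_contributes(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, :, 0] = 1  # every individual heterozygous: p1 = p2 = 0.5
        vt = build_table(gt)
        assert dxy(vt).iloc[0] == pytest.approx(0.5)  # 2 p (1-p)

    def test_per_bp_denominator(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, :6] = 1
        vt = build_table(gt)
        assert dxy(vt, denominator="window_length").iloc[0] == \
            pytest.approx(1.0 / 30_000)

    def test_brute_force_pairwise_oracle(self, m5_table):
        """D_XY equals the mean cross-species pairwise difference."""
        ours = dxy(m5_table, 30_000, "variant_sites")
        gt = m5_table.gt
        h1 = gt[:, :6, :].reshape(gt.shape[0], 12)
        h2 = gt[:, 6:, :].reshape(gt.shape[0], 12)
        per_site = np.array([
            np.mean([a != b for a in row1 for b in row2])
            for row1, row2 in zip(h1, h2)
        ])
        start = (m5_table.pos - 1) // 30_000
        for w, val in zip(ours.index, ours.values):
            mask = (m5_table.chrom == w[0]) & (start * 30_000 == w[1])
            if mask.any():
                assert val == pytest.approx(per_site[mask].mean(), abs=1e-12)


class TestFst:
    def test_reciprocally_fixed_site_is_one(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, :6] = 1
        vt = build_table(gt)
        assert fst_wc(vt).iloc[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(13)
        gt = (rng.random((200, 100, 2)) < 0.5).astype(np.int8)
        vt = build_table(gt, pops=["sp1"] * 50 + ["sp2"] * 50)
        assert abs(fst_wc(vt, 10**7).iloc[0]) < 0.01

    def test_matches_independent_transcription(self, m5_table):
        """Per-site components re-derived independently from first formulas."""
        a, den, usable = fst_wc_sitewise(m5_table)
        gt = m5_table.gt
        for s in range(0, m5_table.n_sites, 37):
            stats = []
            for cols in (slice(0, 6), slice(6, 12)):
                block = gt[s, cols, :]
                ok = (block >= 0).all(axis=1)
                n = ok.sum()
                p = block[ok].mean() if n else np.nan
                h = (block[ok, 0] != block[ok, 1]).mean() if n else np.nan
                stats.append((n, p, h))
            (n1, p1, h1), (n2, p2, h2) = stats
            if n1 < 2 or n2 < 2:
                assert not usable[s]
                continue
            nbar = (n1 + n2) / 2
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a_exp = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
            )
            b_exp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 / 2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_exp = hbar / 2
            assert a[s] == pytest.approx(a_exp, abs=1e-12)
            assert den[s] == pytest.approx(a_exp + b_exp + c_exp, abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_uninformative(self):
        u, z, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_disjoint_small_samples_exact(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_all_tied_p_one(self):
        assert mann_whitney([5, 5], [5, 5, 5])[2] == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(0, 1, 30), rng.normal(0.7, 1, 25)
        assert mann_whitney(x, y)[2] == pytest.approx(mann_whitney(y, x)[2])

    def test_z_grows_with_shift(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 1, 40)
        zs = [abs(mann_whitney(x, x + shift)[1]) for shift in (0.5, 1.5, 3.0)]
        assert zs[0] < zs[1] < zs[2]

    def test_close_to_scipy_large_sample(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(0, 1, 60), rng.normal(0.5, 1, 55)
        _, _, p = mann_whitney(x, y)
        p_ref = mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRareSharing:
    def test_one_copy_in_each_species_is_shared(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, 0, 0] = 1   # sp1
        gt[0, 7, 0] = 1   # sp2
        res = rare_shared_fraction(build_table(gt))
        assert (res.n_rare, res.n_shared) == (1, 1)

    def test_both_copies_in_one_species_not_shared(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, 0] = 1
        res = rare_shared_fraction(build_table(gt))
        assert (res.n_rare, res.n_shared) == (1, 0)

    def test_singletons_and_common_sites_not_rare(self):
        gt = np.zeros((3, 12, 2), dtype=np.int8)
        gt[0, 0, 0] = 1          # singleton
        gt[1, :, :] = 1
        gt[1, :3, :] = 0         # minor count 6 > 5
        gt[2, :4, 0] = 1         # count 4: rare
        res = rare_shared_fraction(build_table(gt))
        assert res.n_rare == 1

    def test_no_rare_sites_undefined(self):
        gt = np.zeros((1, 12, 2), dtype=np.int8)
        gt[0, :, 0] = 1
        res = rare_shared_fraction(build_table(gt))
        assert res.n_rare == 0 and np.isnan(res.proportion)

    def test_gene_flow_increases_sharing(self):
        """Recent migration leaves shared rare variants (paired seeds)."""
        from divflow.coalescent import SimConfig, make_model
        from divflow.synthetic import genotypes_from_model

        cfg = SimConfig(12, 12, mu=1e-8, locus_length=1000, n_loci=60,
                        seed=31)
        wins = 0
        for seed in (31, 32, 33):
            cfg_s = SimConfig(12, 12, mu=1e-8, locus_length=1000, n_loci=60,
                              seed=seed)
            f5 = rare_shared_fraction(genotypes_from_model(
                make_model("M5", m=5e-5), cfg_s)).proportion
            f1 = rare_shared_fraction(genotypes_from_model(
                make_model("M1"), cfg_s)).proportion
            wins += int(f5 > f1)
        assert wins >= 2


class TestScanAndClassification:
    def test_window_tiling_and_flags(self, m5_table):
        df = scan(m5_table)
        for chrom, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            assert (np.diff(starts) == 30_000).all()
            assert grp["partial"].iloc[-1]
        assert df["n_var"].sum() == m5_table.n_sites
        ok = df["dxy"].notna()
        assert (df.loc[ok, "early"] == (df.loc[ok, "dxy"] >= 0.35)).all()

    def test_early_threshold_boundary(self):
        import pandas as pd

        df = pd.DataFrame({
            "chrom": ["c"] * 3, "start": [0, 1, 2], "end": [1, 2, 3],
            "dxy": [0.36, 0.35, 0.10],
        })
        out = classify_early(df)
        assert list(out["early"]) == [True, True, False]

    def test_deep_split_dxy_exceeds_diversity(self):
        """Under long isolation, between-species divergence dwarfs
        within-species diversity."""
        from divflow.coalescent import SimConfig, make_model
        from divflow.synthetic import genotypes_from_model

        cfg = SimConfig(12, 12, mu=1e-8, locus_length=1000, n_loci=80,
                        seed=41)
        vt = genotypes_from_model(make_model("M1", T_split=2e6), cfg)
        df = scan(vt, pi_denominator="window_length",
                  dxy_denominator="window_length")
        assert np.nanmean(df["dxy"]) > np.nanmean(df["pi1"])
        assert np.nanmean(df["dxy"]) > np.nanmean(df["pi2"])
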