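"""Hard filters, LD pruning, fourfold-degenerate extraction, subsetting."""

import numpy as np
import pytest

from divflow.io import write_gff3
from divflow.synthetic import NoiseConfig, inject_noise
from divflow.variants import (
    SiteFilterConfig,
    filter_sites,
    fourfold_degenerate_sites,
    ld_prune,
    read_vcf,
    subset_samples,
    subset_sites,
    write_vcf,
)

from conftest import build_table


def _polymorphic_gt(n, n_alt=12):
    """One-site genotype block with ``n_alt`` alt alleles spread over calls."""
    gt = np.zeros((1, n, 2), dtype=np.int8)
    gt.reshape(1, -1)[0, :n_alt] = 1
    return gt


class TestFilterSites:
    def test_three_of_24_missing_exceeds_tolerance(self):
        gt = _polymorphic_gt(24)
        gt[0, :3] = -1
        vt = build_table(gt)
        assert filter_sites(vt).n_sites == 0

    def test_two_of_24_missing_is_tolerated(self):
        gt = _polymorphic_gt(24)
        gt[0, :2] = -1
        vt = build_table(gt)
        assert filter_sites(vt).n_sites == 1

    def test_gq_masking_feeds_missingness_rule(self):
        """Low-GQ calls are masked first, then counted as missing."""
        gt = _polymorphic_gt(24)
        vt = build_table(gt)
        vt.gq[0, :4] = 10  # 4/24 = 16.7% masked -> site fails
        out, mask = filter_sites(vt, return_mask=True)
        assert out.n_sites == 0 and not mask[0]

    @pytest.mark.parametrize(
        "dp, kept", [(9, False), (10, True), (50, True), (51, False), (30, True)]
    )
    def test_mean_depth_bounds_inclusive(self, dp, kept):
        vt = build_table(_polymorphic_gt(24), dp=dp)
        assert filter_sites(vt).n_sites == int(kept)

    def test_low_maf_dropped(self):
        vt = build_table(_polymorphic_gt(24, n_alt=4))  # maf 4/48 = 0.083
        assert filter_sites(vt).n_sites == 0
        vt = build_table(_polymorphic_gt(24, n_alt=5))  # 5/48 = 0.104
        assert filter_sites(vt).n_sites == 1

    def test_empty_table_passes_through(self):
        vt = build_table(np.zeros((0, 24, 2), dtype=np.int8))
        assert filter_sites(vt).n_sites == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SiteFilterConfig(max_missing_frac=1.5)
        with pytest.raises(ValueError):
            SiteFilterConfig(min_maf=0.7)

    def test_idempotent_on_noisy_fixture(self, m5_table):
        rng = np.random.default_rng(0)
        noisy, _ = inject_noise(
            m5_table, NoiseConfig(0.1, 0.1, 0.1, 0.05), rng
        )
        once = filter_sites(noisy)
        twice = filter_sites(once)
        assert list(twice.pos) == list(once.pos)
        assert np.array_equal(twice.gt, once.gt)

    def test_survivors_match_truth_sidecar(self, m5_table):
        rng = np.random.default_rng(1)
        noisy, truth = inject_noise(
            m5_table, NoiseConfig(0.15, 0.1, 0.1, 0.05), rng
        )
        kept = filter_sites(noisy)
        got = set(zip(kept.chrom, (int(p) for p in kept.pos)))
        assert got == set(truth.surviving_sites)


class TestLDPrune:
    def test_duplicated_site_collapses_to_one(self):
        gt = np.repeat(_polymorphic_gt(24), 2, axis=0)
        vt = build_table(gt, pos=[10, 20])
        assert len(ld_prune(vt)) == 1

    def test_independent_sites_all_kept(self):
        rng = np.random.default_rng(3)
        # independent binomial dosages: expected r2 ~ 1/n, well under 0.1
        gt = (rng.random((40, 200, 2)) < 0.4).astype(np.int8)
        vt = build_table(gt, pops=["sp1"] * 100 + ["sp2"] * 100)
        assert len(ld_prune(vt)) == 40

    def test_no_retained_pair_exceeds_threshold(self, m5_table):
        """Brute-force check over every retained within-window pair."""
        vt = subset_sites(m5_table, np.arange(100))
        kept = ld_prune(vt, window_snps=50, step_snps=10, r2_max=0.1)
        dos = vt.dosage()
        kept_sorted = np.sort(kept)
        for wstart in range(0, 100, 10):
            window = [i for i in kept_sorted if wstart <= i < wstart + 50]
            for ai in range(len(window)):
                for bi in range(ai + 1, len(window)):
                    x, y = dos[window[ai]], dos[window[bi]]
                    ok = ~np.isnan(x) & ~np.isnan(y)
                    if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                        continue
                    r = np.corrcoef(x[ok], y[ok])[0, 1]
                    assert r * r <= 0.1 + 1e-12

    def test_pruning_stable_within_a_window_span(self):
        """Within one window the kept set is a fixed point: pruning it again
        removes nothing.  (Across windows, re-packing survivors can expose
        new pairs — the documented single-pass behaviour.)"""
        rng = np.random.default_rng(12)
        base = (rng.random((1, 40, 2)) < 0.5).astype(np.int8)
        gt = np.repeat(base, 50, axis=0)
        flip = rng.random((50, 40, 2)) < 0.45  # partially correlated sites
        gt = np.where(flip, 1 - gt, gt).astype(np.int8)
        vt = build_table(gt, pops=["sp1"] * 20 + ["sp2"] * 20)
        kept = ld_prune(vt)
        pruned = subset_sites(vt, kept)
        assert len(ld_prune(pruned)) == len(kept)

    def test_output_subset_of_input(self, m5_table):
        kept = ld_prune(subset_sites(m5_table, np.arange(60)))
        assert set(kept) <= set(range(60))


class TestFourfold:
    def _write(self, tmp_path, ref, rows):
        gff = tmp_path / "g.gff3"
        write_gff3(rows, gff)
        return ref, gff

    def test_fourfold_family_codons(self, tmp_path):
        # GGA GGT CTC: Gly, Gly, Leu -> third positions all fourfold
        seq = "NN" + "GGAGGTCTC" + "NN"
        ref, gff = self._write(
            tmp_path, {"c": seq},
            [("c", "t", "CDS", 3, 11, ".", "+", "0", "ID=g1")],
        )
        sites = fourfold_degenerate_sites(ref, gff)
        assert list(sites["c"]) == [5, 8, 11]

    def test_nondegenerate_codons_yield_nothing(self, tmp_path):
        ref, gff = self._write(
            tmp_path, {"c": "ATGTGGTAA"},
            [("c", "t", "CDS", 1, 9, ".", "+", "0", "ID=g1")],
        )
        sites = fourfold_degenerate_sites(ref, gff)
        assert len(sites.get("c", [])) == 0

    def test_minus_strand_same_genomic_positions(self, tmp_path):
        plus = "GGAGGTCTC"
        minus = "GAGACCTCC"  # reverse complement of plus
        ref_p, gff_p = self._write(
            tmp_path, {"c": "NN" + plus + "NN"},
            [("c", "t", "CDS", 3, 11, ".", "+", "0", "ID=g1")],
        )
        got_p = fourfold_degenerate_sites(ref_p, gff_p)["c"]
        gff_m = tmp_path / "m.gff3"
        write_gff3([("c", "t", "CDS", 3, 11, ".", "-", "0", "ID=g1")], gff_m)
        got_m = fourfold_degenerate_sites({"c": "NN" + minus + "NN"}, gff_m)["c"]
        # mirrored genomic coordinates of the same codon third positions
        assert list(got_m) == [3, 6, 9]
        assert list(got_p) == [5, 8, 11]

    def test_internal_stop_skips_gene(self, tmp_path):
        ref, gff = self._write(
            tmp_path, {"c": "GGATAAGGA"},
            [("c", "t", "CDS", 1, 9, ".", "+", "0", "ID=g1")],
        )
        with pytest.warns(UserWarning, match="internal stop"):
            sites = fourfold_degenerate_sites(ref, gff)
        assert len(sites.get("c", [])) == 0

    def test_overlapping_genes_must_agree(self, tmp_path):
        # frame-shifted overlap: position fourfold in one frame only
        seq = "GGAGGAGGA" + "T"
        gff = tmp_path / "o.gff3"
        write_gff3(
            [
                ("c", "t", "CDS", 1, 9, ".", "+", "0", "ID=g1"),
                ("c", "t", "CDS", 2, 10, ".", "+", "0", "ID=g2"),
            ],
            gff,
        )
        sites = fourfold_degenerate_sites({"c": seq}, gff)
        own = {3, 6, 9}  # g1's fourfold thirds
        assert set(sites["c"]) <= own

    def test_brute_force_retranslation_oracle(self, tmp_path, coding_fixture):
        """Every reported site, mutated to any base, preserves the protein;
        every unreported CDS site does not (single-frame genes)."""
        from divflow.variants import cds_layout, _TRANSLATE

        gff = tmp_path / "f.gff3"
        write_gff3(coding_fixture.gff3, gff)
        ref = coding_fixture.ref
        sites = fourfold_degenerate_sites(ref, gff)
        reported = {int(p) for p in sites.get("chrG", [])}

        def protein(cds):
            return "".join(
                _TRANSLATE[cds[i:i + 3]] for i in range(0, len(cds), 3)
            )

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for gid, (chrom, strand, phase, segs) in cds_layout(gff).items():
            (s, e), = segs
            seq = ref[chrom]
            for gpos in range(s, e + 1):
                cds = seq[s - 1:e]
                if strand == "-":
                    cds = "".join(comp[b] for b in reversed(cds))
                    k = e - gpos
                else:
                    k = gpos - s
                base_prot = protein(cds)
                invariant = True
                for b in "ACGT":
                    mutated = cds[:k] + b + cds[k + 1:]
                    if protein(mutated) != base_prot:
                        invariant = False
                        break
                assert invariant == (gpos in reported), (gid, gpos)


class TestSubsetting:
    def test_identity_and_empty(self, m5_table):
        same = subset_sites(m5_table, np.arange(m5_table.n_sites))
        assert np.array_equal(same.gt, m5_table.gt)
        empty = subset_sites(m5_table, np.array([], dtype=int))
        assert empty.n_sites == 0

    def test_sample_subset_and_unknown_id(self, m5_table):
        ids = m5_table.samples[:3]
        sub = subset_samples(m5_table, ids)
        assert sub.samples == ids and sub.gt.shape[1] == 3
        with pytest.raises(KeyError):
            subset_samples(m5_table, ["nope"])

    def test_seeded_draw_reproducible(self, m5_table):
        a = np.random.default_rng(9).choice(m5_table.samples, 6, replace=False)
        b = np.random.default_rng(9).choice(m5_table.samples, 6, replace=False)
        assert np.array_equal(
            subset_samples(m5_table, list(a)).gt,
            subset_samples(m5_table, list(b)).gt,
        )


def test_vcf_round_trip(tmp_path, m5_table):
    rng = np.random.default_rng(4)
    noisy, _ = inject_noise(m5_table, NoiseConfig(0.1, 0.1, 0.1, 0.0), rng)
    path = tmp_path / "t.vcf"
    write_vcf(noisy, path)
    back = read_vcf(path, dict(zip(noisy.samples, noisy.pops)))
    assert back.samples == noisy.samples
    assert np.array_equal(back.gt, noisy.gt)
    assert np.array_equal(back.dp, noisy.dp)
    assert np.array_equal(back.gq, noisy.gq)
    assert list(back.pos) == list(noisy.pos)
    assert list(back.pops) == list(noisy.pops)
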