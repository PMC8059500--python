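"""Canned study-scale experiments on synthetic data with known truth.

These are the package's headline computations wired end to end at desk
scale: theory checks for the coalescent engine, the ABC model-recovery
experiment, neutral calibration of the window scan and the MKT stage, and
the full synthetic pipeline (fixtures -> filters -> pruning -> fourfold
restriction -> observed SFS -> ABC -> genome scan -> MKT -> early-window
intersection).  Problem sizes default to values that run in minutes on one
CPU; every function is deterministic given its seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .coalescent import (
    DemographicModel,
    SimConfig,
    drop_mutations,
    make_model,
    simulate_genealogy,
    simulate_joint_sfs,
)
from .mkt import (
    GeneAlignment,
    gene_alignments_from_table,
    genes_in_early_windows,
    mkt_scan,
)
from .sfs_abc import PriorSpec, abc_model_select, simulate_reference_table
from .synthetic import (
    NoiseConfig,
    fourfold_reference_for,
    genotypes_from_model,
    inject_noise,
    make_coding_fixture,
)
from .variants import (
    filter_sites,
    fourfold_degenerate_sites,
    ld_prune,
    subset_sites,
)
from .windows import rare_shared_fraction, scan, tajimas_d

__all__ = [
    "panmictic_neutral_check",
    "deep_split_dxy_check",
    "recovery_priors",
    "abc_recovery_experiment",
    "neutral_tajima_windows",
    "mkt_neutral_fpr",
    "end_to_end_pipeline",
]

# divergence presets used as the generating truth in recovery experiments:
# split 1 Ma at one generation per year, contemporary sizes 1e5, ancestral
# 5e5 diploids, symmetric migration 2e-5 per lineage per generation
TRUE_PARAMS = dict(T_split=1e6, N1=1e5, N2=1e5, N_anc=5e5, m=2e-5)


def panmictic_neutral_check(
    seed: int, n: int = 12, N: float = 1e4, theta: float = 1.0,
    n_loci: int = 5000,
):
    """Panmictic-limit calibration of the engine against neutral theory.

    Simulates ``n_loci`` unlinked loci for ``n`` haploid samples from a
    single population (a vanishing split) with per-locus theta = 4 N mu L,
    and summarizes the frequency spectrum, diversity and segregating sites
    against E[xi_i] = theta/i, E[pi] = theta, E[S] = theta * a1.
    """
    mu_L = theta / (4 * N)
    model = DemographicModel("custom", 1.0, N, N, N, ())
    rng = np.random.default_rng(seed)
    n_half = n // 2
    xi = np.zeros((n_loci, n - 1))
    pi = np.zeros(n_loci)
    for rep in range(n_loci):
        g = simulate_genealogy(model, n_half, n - n_half, rng)
        for d1, d2 in drop_mutations(g, mu_L, 1, rng):
            d = d1 + d2
            xi[rep, d - 1] += 1
            pi[rep] += 2.0 * d * (n - d) / (n * (n - 1.0))
    S = xi.sum(axis=1)
    a1 = (1.0 / np.arange(1, n)).sum()
    return {
        "n": n, "n_loci": n_loci, "theta": theta, "a1": a1,
        "xi_mean": xi.mean(0),
        "xi_se": xi.std(0, ddof=1) / np.sqrt(n_loci),
        "xi_expected": theta / np.arange(1, n),
        "pi_mean": float(pi.mean()),
        "pi_se": float(pi.std(ddof=1) / np.sqrt(n_loci)),
        "S_mean": float(S.mean()),
        "S_se": float(S.std(ddof=1) / np.sqrt(n_loci)),
        "S_expected": float(theta * a1),
    }


def deep_split_dxy_check(
    seed: int, T_split: float = 1e6, N_anc: float = 5e5, mu: float = 1e-8,
    L: int = 1000, n_loci: int = 5000,
):
    """Isolation closed form: E[D_XY per bp] = 2 mu (T_split + 2 N_anc)."""
    model = make_model("M1", T_split, 1e5, 1e5, N_anc, 0.0)
    rng = np.random.default_rng(seed)
    per_locus = np.zeros(n_loci)
    for rep in range(n_loci):
        g = simulate_genealogy(model, 2, 2, rng)
        for d1, d2 in drop_mutations(g, mu, L, rng):
            p1, p2 = d1 / 2.0, d2 / 2.0
            per_locus[rep] += p1 * (1 - p2) + p2 * (1 - p1)
    per_locus /= L
    return {
        "n_loci": n_loci,
        "dxy_mean": float(per_locus.mean()),
        "dxy_se": float(per_locus.std(ddof=1) / np.sqrt(n_loci)),
        "dxy_expected": float(2 * mu * (T_split + 2 * N_anc)),
    }


def recovery_priors() -> PriorSpec:
    """Priors of the model-recovery experiment: moderately wide windows
    around the generating presets (sizes log-uniform within a factor ~4,
    migration uniform over half an order of magnitude each way)."""
    return PriorSpec({
        "T_split": ("fixed", TRUE_PARAMS["T_split"]),
        "N1": ("loguniform", 5e4, 2e5),
        "N2": ("loguniform", 5e4, 2e5),
        "N_anc": ("loguniform", 2e5, 1e6),
        "m": ("uniform", 5e-6, 5e-5),
    })


def _pseudo_observed(label: str, cfg: SimConfig, seed: int):
    model = make_model(label, **TRUE_PARAMS) if label != "M1" else \
        make_model("M1", TRUE_PARAMS["T_split"], TRUE_PARAMS["N1"],
                   TRUE_PARAMS["N2"], TRUE_PARAMS["N_anc"], 0.0)
    return simulate_joint_sfs(model, cfg, np.random.default_rng(seed)).fold()


def abc_recovery_experiment(
    seed: int,
    n_sims_per_model: int = 2000,
    n_pseudo: int = 20,
    n_loci: int = 50,
    tolerance: float = 0.005,
):
    """Can rejection ABC tell the divergence scenarios apart?

    Builds a pooled reference table (all five scenarios, recovery priors,
    folded 7x7 spectra from ``n_loci`` kb-scale loci per simulation), then
    (a) pits pseudo-observed data generated under M1 and under M5 against
    the M1/M5 rows and counts how often the generating scenario tops the
    acceptance-proportion ranking, and (b) for pseudo-observed data under
    each gene-flow scenario (M2-M5) checks whether the summed acceptance
    proportion of gene-flow scenarios exceeds complete isolation's.
    """
    cfg = SimConfig(6, 6, mu=2e-8, locus_length=1000, n_loci=n_loci)
    rng = np.random.default_rng(seed)
    ref = simulate_reference_table(
        ["M1", "M2", "M3", "M4", "M5"], recovery_priors(),
        n_sims_per_model, cfg, rng,
    )
    pair = ref[ref["model"].isin(["M1", "M5"])].reset_index(drop=True)

    top_rank = {}
    for gen in ("M1", "M5"):
        wins = 0
        for i in range(n_pseudo):
            obs = _pseudo_observed(gen, cfg, seed + 1000 + i)
            wins += abc_model_select(obs, pair, tolerance).best_model == gen
        top_rank[gen] = wins

    flow_wins = {}
    m5_proportions = None
    for gen in ("M2", "M3", "M4", "M5"):
        wins = 0
        for i in range(n_pseudo):
            obs = _pseudo_observed(gen, cfg, seed + 3000 + i)
            res = abc_model_select(obs, ref, tolerance)
            wins += (1.0 - res.proportions["M1"]) > res.proportions["M1"]
            if gen == "M5" and i == 0:
                m5_proportions = dict(res.proportions)
        flow_wins[gen] = wins
    return {
        "n_sims_per_model": n_sims_per_model,
        "n_pseudo": n_pseudo,
        "tolerance": tolerance,
        "top_rank_wins": top_rank,
        "flow_beats_isolation": flow_wins,
        "example_m5_proportions": m5_proportions,
    }


def neutral_tajima_windows(seed: int, n_windows: int = 150):
    """Windowed Tajima's D on neutral constant-size data.

    15 unlinked kb loci per 30 kb window, 24 haploid genomes from one
    panmictic population of 1e5 diploids; summarizes the D distribution of
    the first species label (all samples are exchangeable).
    """
    N = 1e5
    model = DemographicModel("custom", 1.0, N, N, N, ())
    n_loci = 15 * n_windows
    cfg = SimConfig(12, 12, mu=1e-8, locus_length=1000, n_loci=n_loci,
                    seed=seed)
    layout = [("chr1", 2 * n_loci * 1000 + 1000)]
    vt = genotypes_from_model(model, cfg, layout,
                              rng=np.random.default_rng(seed))
    d = tajimas_d(vt, "sp1").dropna()
    return {
        "n_windows": int(len(d)),
        "mean_d": float(d.mean()),
        "frac_within_pm2": float(((d > -2) & (d < 2)).mean()),
    }


def mkt_neutral_fpr(seed: int, n_genes: int = 500, lam: float = 20.0):
    """Fisher false-positive rate on genes with no planted selection.

    Per gene the four MKT cells are independent Poisson draws with a common
    mean, so the null (equal non-synonymous/synonymous odds in polymorphism
    and divergence) holds; the exact test should reject at most ~5% of
    genes at alpha = 0.05 (conservatively fewer, being an exact
    conditional test).
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(n_genes, 4))
    fx = make_coding_fixture([tuple(int(x) for x in c) for c in counts],
                             rng=rng)
    aligns = [GeneAlignment(g, fx.alignments[g]) for g in fx.alignments]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = mkt_scan(aligns)
    assert np.array_equal(
        df[["Dn", "Ds", "Pn", "Ps"]].to_numpy(), counts
    ), "planted counts not recovered"
    return {
        "n_genes": n_genes,
        "fpr": float((df["p_fisher"] < 0.05).mean()),
    }


def end_to_end_pipeline(
    seed: int,
    n_loci: int = 200,
    n_sims_per_model: int = 400,
    abc_loci: int = 50,
    tolerance: float = 0.01,
):
    """Full synthetic pipeline under continuous gene flow (M5 truth).

    fixtures -> noise -> hard filters (checked against the truth sidecar)
    -> LD pruning -> fourfold-degenerate restriction (variants sit inside
    synthetic genes) -> folded observed joint SFS (6 individuals per
    species) -> rejection ABC over the five scenarios -> 30 kb genome scan
    with early-window classification -> per-gene MKT on the same genes ->
    intersection of positively selected genes with early windows ->
    rare-allele sharing, contrasted with an isolation run.
    """
    truth_model = make_model("M5", **TRUE_PARAMS)
    cfg = SimConfig(12, 12, mu=1e-8, locus_length=1000, n_loci=n_loci,
                    seed=seed)
    per_chrom = (n_loci // 2 + 1) * 2000 + 1000
    layout = [("chr1", per_chrom), ("chr2", per_chrom)]
    rng = np.random.default_rng(seed)
    vt_clean = genotypes_from_model(truth_model, cfg, layout, rng)
    ref_genome, gff_rows = fourfold_reference_for(
        vt_clean, cfg, layout, rng
    )
    noisy, truth = inject_noise(
        vt_clean, NoiseConfig(0.05, 0.05, 0.05, 0.03), rng
    )

    filtered = filter_sites(noisy)
    got = set(zip(filtered.chrom, (int(p) for p in filtered.pos)))
    filter_matches_truth = got == set(truth.surviving_sites)

    kept_idx = ld_prune(filtered)
    pruned = subset_sites(filtered, kept_idx)

    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".gff3",
                                     delete=False) as fh:
        fh.write("##gff-version 3\n")
        for row in gff_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
        gff_path = fh.name
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ff_sites = fourfold_degenerate_sites(ref_genome, gff_path)
    ff_lookup = {c: set(map(int, v)) for c, v in ff_sites.items()}
    ff_mask = np.array([
        int(p) in ff_lookup.get(c, ()) for c, p in
        zip(pruned.chrom, pruned.pos)
    ], dtype=bool)
    neutral_sites = subset_sites(pruned, np.nonzero(ff_mask)[0])

    from .sfs_abc import observed_joint_sfs

    obs = observed_joint_sfs(
        neutral_sites, k=6, mode="subsample", fold=True,
        rng=np.random.default_rng(seed + 1),
    )
    abc_cfg = SimConfig(12, 12, mu=2e-8, locus_length=1000, n_loci=abc_loci)
    ref_table = simulate_reference_table(
        ["M1", "M2", "M3", "M4", "M5"], recovery_priors(),
        n_sims_per_model, abc_cfg, np.random.default_rng(seed + 2),
    )
    abc_res = abc_model_select(obs, ref_table, tolerance)

    windows = scan(filtered)
    early = windows[windows["early"].fillna(False)]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligns = gene_alignments_from_table(filtered, ref_genome, gff_path)
        mkt_df = mkt_scan(aligns)
    from .variants import cds_layout

    coords = {
        gid: (chrom, strand, segs)
        for gid, (chrom, strand, _, segs) in cds_layout(gff_path).items()
    }
    pos_in_early = genes_in_early_windows(mkt_df, coords, windows)

    rare_m5 = rare_shared_fraction(filtered)
    iso_vt = genotypes_from_model(
        make_model("M1", TRUE_PARAMS["T_split"], TRUE_PARAMS["N1"],
                   TRUE_PARAMS["N2"], TRUE_PARAMS["N_anc"], 0.0),
        cfg, layout, np.random.default_rng(seed),
    )
    rare_m1 = rare_shared_fraction(iso_vt)

    gene_flow_share = 1.0 - abc_res.proportions["M1"]
    return {
        "seed": seed,
        "n_sites_simulated": int(noisy.n_sites),
        "n_sites_filtered": int(filtered.n_sites),
        "filter_matches_truth": bool(filter_matches_truth),
        "n_sites_pruned": int(pruned.n_sites),
        "n_sites_fourfold": int(neutral_sites.n_sites),
        "obs_sfs_sites": float(obs.n_sites),
        "abc_proportions": dict(abc_res.proportions),
        "abc_best_model": abc_res.best_model,
        "abc_gene_flow_share": float(gene_flow_share),
        "n_windows": int(len(windows)),
        "n_early_windows": int(len(early)),
        "mean_dxy": float(np.nanmean(windows["dxy"])),
        "mean_fst": float(np.nanmean(windows["fst"])),
        "mean_pi1_per_bp": float(np.nanmean(windows["pi1"])),
        "mean_td1": float(np.nanmean(windows["td1"])),
        "n_genes_tested": int(len(mkt_df)),
        "n_genes_positive": int((mkt_df["sel_class"] == "positive").sum()),
        "n_genes_negative": int((mkt_df["sel_class"] == "negative").sum()),
        "n_positive_in_early": int(len(pos_in_early)),
        "rare_share_m5": float(rare_m5.proportion),
        "rare_share_m1": float(rare_m1.proportion),
    }
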