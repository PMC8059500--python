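# divflow

Divergence-with-gene-flow analysis for a pair of sister species from
whole-genome SNP data: did the two lineages separate in complete isolation,
or did they keep exchanging migrants — and when?

`divflow` bundles the full analysis chain a population geneticist needs to
ask that question, together with a synthetic-data generator that makes every
stage testable against known ground truth:

- a **two-deme structured-coalescent simulator** (piecewise-constant
  migration epochs, ancestral merge, infinite-sites mutations) producing
  joint site-frequency spectra under five canonical divergence scenarios —
  complete isolation (M1), gene flow until 200 kya (M2), secondary contact
  100–10 kya (M3), secondary contact 150–100 kya (M4), and continuous gene
  flow until 10 kya (M5);
- **rejection-ABC model selection** on the joint SFS, reported as each
  scenario's share of the accepted simulations;
- **variant curation**: hard site filters (GQ < 30 masking, >10% missing,
  mean depth outside [10, 50], MAF < 0.1), PLINK-style
  `--indep-pairwise 50 10 0.1` LD pruning, and fourfold-degenerate-site
  extraction from a reference + GFF3 annotation;
- a **30 kb windowed genome scan**: per-species nucleotide diversity π and
  Tajima's D, between-species absolute divergence D_XY and Weir–Cockerham
  F_ST, Mann–Whitney species contrasts, classification of early-diverged
  windows (W_early: D_XY ≥ 0.35), and the rare-allele sharing statistic
  (minor-allele count 2–5) that flags recent gene flow;
- per-gene **McDonald–Kreitman tests** (Dn/Ds/Pn/Ps, Fisher's exact test,
  neutrality index NI = (Pn/Ps)/(Dn/Ds), α = 1 − NI) and the intersection
  of positively selected genes with W_early windows.

## The model in brief

Backwards in time, lineages sampled from two demes of diploid sizes
N₁ and N₂ coalesce within a deme at rate k(k−1)/(4N) and migrate between
demes at the per-lineage rate of the current epoch; at T_split all lineages
merge into an ancestral deme of size N_anc. Mutations are dropped on
branches at rate μ per bp per generation (one biallelic site each). The
observed joint SFS — built from six individuals per species, on filtered,
LD-pruned, fourfold-degenerate SNPs — is compared with simulated spectra by
Euclidean distance between mass-normalized matrices; the closest fraction
(tolerance) of the pooled simulations is accepted, and each scenario's
acceptance share is its model-choice score.

## Worked example

```python
import numpy as np
from divflow import (make_model, SimConfig, genotypes_from_model, filter_sites,
                     ld_prune, subset_sites, observed_joint_sfs,
                     ABCModelSelection, PriorSpec)
from divflow.windows import scan, rare_shared_fraction

# two species that split 1 Ma ago and kept exchanging migrants until 10 kya
truth = make_model("M5", T_split=1e6, N1=1e5, N2=1e5, N_anc=5e5, m=2e-5)
cfg = SimConfig(n1=12, n2=12, mu=1e-8, locus_length=1000, n_loci=200, seed=7)
vt = genotypes_from_model(truth, cfg, rng=np.random.default_rng(7))
print(f"{vt.n_sites} SNPs for {vt.n_samples} diploid individuals")

kept = filter_sites(vt)
pruned = subset_sites(kept, ld_prune(kept))
print(f"{kept.n_sites} pass hard filters; {pruned.n_sites} after LD pruning")

obs = observed_joint_sfs(pruned, k=6, fold=True, rng=np.random.default_rng(1))
sel = ABCModelSelection(obs, priors=PriorSpec(),
                        cfg=SimConfig(12, 12, mu=2e-8, n_loci=50))
res = sel.fit(n_sims_per_model=400, tolerance=0.01, seed=11)
print(res.summary())

windows = scan(kept)
rare = rare_shared_fraction(kept)
print(f"{len(windows)} windows, {int(windows['early'].sum())} early-diverged "
      f"(D_XY >= 0.35); mean D_XY = {np.nanmean(windows['dxy']):.3f}")
print(f"rare-allele sharing: {rare.proportion:.2%} of {rare.n_rare} rare SNPs")
```

prints

```
6811 SNPs for 12 diploid individuals
4197 pass hard filters; 164 after LD pruning
Rejection-ABC model selection
==============================================
tolerance: 0.01   accepted: 20 of 2000
model    simulated  accepted  proportion
----------------------------------------------
M3             400        13      65.0%
M5             400         4      20.0%
M4             400         3      15.0%
M1             400         0       0.0%
M2             400         0       0.0%
----------------------------------------------
14 windows, 14 early-diverged (D_XY >= 0.35); mean D_XY = 0.405
rare-allele sharing: 63.25% of 1630 rare SNPs
```

Reading the output: all accepted simulations come from gene-flow scenarios
(M3/M4/M5), so isolation is clearly rejected — correct, since the data were
generated under M5. At this small data size the three secondary-contact
variants remain mutually confusable (their spectra differ only through the
timing of migration), which is exactly the behaviour the acceptance-share
presentation is designed to expose. The high mean D_XY (per variant site)
reflects the deep split, and the strong rare-allele sharing is the signature
of the continuous migration in the generating model.

A thin CLI mirrors the library: `divflow simulate | fixtures | filter |
prune | fourfold | sfs | abc-select | scan | mkt` (see `divflow --help`).

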