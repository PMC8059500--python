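# Methods

## Coalescent engine

The simulator implements the structured coalescent for two contemporary
demes plus an ancestral deme, in continuous time measured in generations
before present. With kᵢ lineages in deme i of diploid size Nᵢ, within-deme
coalescence occurs at rate kᵢ(kᵢ−1)/(4Nᵢ); each lineage in deme 1 moves
(backwards in time) to deme 2 at the rate m₁₂ of the migration epoch
containing the current time, and symmetrically for m₂₁. Outside every epoch
the migration rate is zero. At T_split all lineages transfer to the
ancestral deme of size N_anc. Waiting times are exponential with the total
rate of the current state and are re-drawn whenever the process crosses an
epoch boundary or the split time; by memorylessness this re-draw is exact,
so no time discretization is involved. Epochs whose two rates are both zero
are dropped at model construction — they cannot affect the law of the
process, and removing them keeps the event stream identical to the
epoch-free model under a shared seed.

Mutations follow the infinite-sites model: each branch receives a Poisson
number of mutations with mean (branch length × μ × L), equivalent to
placing a Poisson(total length × μL) total proportionally to branch length.
Each mutation defines one biallelic site whose derived allele is carried by
the leaves below the branch. There is no recombination within a locus and
free recombination between loci; SFS summaries depend on per-locus
genealogies only through their marginal distribution, so intra-locus
linkage does not bias the expected spectrum.

Scenario presets (all times in generations, one generation per year):
M1 no migration; M2 epoch [200 000, T_split]; M3 [10 000, 100 000];
M4 [100 000, 150 000]; M5 [10 000, T_split]; presets use symmetric rates
(m₁₂ = m₂₁), asymmetric rates are available through custom models. Default
anchor parameters are T_split = 10⁶, N₁ = N₂ = 10⁵, N_anc = 5×10⁵ diploids
and μ = 10⁻⁸ per bp per generation; these are the generating "truth" used
throughout the synthetic experiments.

Two haploid lineages per diploid individual are paired in sampling order
(lineages 2i, 2i+1 form individual i). A single seeded NumPy generator is
threaded through every stochastic call, so identical seeds give
bit-identical output.

## Joint SFS, folding, projection

The joint SFS is a (n₁+1)×(n₂+1) count matrix over derived-allele count
pairs; cells (0,0) and (n₁,n₂) are structurally empty for unfolded spectra.
Folding merges (i,j) with (n₁−i, n₂−j), assigning the mass to the
configuration with the smaller total allele count and, on exact ties, to
the lexicographically smaller index pair — a deterministic, idempotent
rule. The default polarization in the inference layer is folded, since
real data rarely come with a trusted outgroup polarization; the synthetic
generator writes the ancestral allele as the reference allele, so unfolded
spectra are exact there, and a mis-polarization scrambler exists to
exercise folding.

The observed SFS supports two constructions: seeded subsampling of k
individuals per species (sites with any missing call in the draw are
dropped) and hypergeometric down-projection of each site's allele counts
to 2k alleles per species (sites with fewer than 2k called alleles in
either species are skipped). Subsampling is the default; with six
individuals per species it mirrors the intended study design.

## Rejection ABC

Spectra are compared by the Euclidean distance between mass-normalized
matrices with the two structural corner cells removed; normalization makes
the distance invariant to the number of segregating sites a simulation
happens to produce. The accepted set is the round(tolerance × N) pooled
simulations with the smallest distances (at least one), and each scenario's
score is its share of that set; shares sum to one by construction. Default
tolerance is 0.005; both the distance and the tolerance are configurable.
Parameter priors are explicit configuration: the package defaults are
weakly informative (sizes log-uniform on [10⁴, 10⁷], migration uniform on
[0, 10⁻⁴], T_split fixed at 10⁶). The recovery experiment instead draws
from moderate windows around the generating presets (sizes log-uniform
within roughly a factor of four, migration uniform on [5×10⁻⁶, 5×10⁻⁵]):
its purpose is to measure scenario identifiability at desk scale, which
requires the generating values to be inside, not dwarfed by, the prior
mass. Posterior summaries (mean, median, central 95% interval) are computed
over accepted draws per scenario, as in standard rejection ABC.

## Variant filters and pruning

Filter order is fixed and documented: (1) calls with GQ below 30 are masked
to missing; (2) sites with a missing-call fraction above 0.10 are dropped;
(3) sites whose mean depth over non-missing calls falls outside [10, 50]
are dropped; (4) sites with minor-allele frequency below 0.10 over
non-missing alleles are dropped. Masking precedes the site rules, so
low-quality calls count as missing everywhere downstream — the natural
reading of applying a call mask and site filters "simultaneously", made
explicit because GQ masking changes the missingness and frequency
denominators.

LD pruning follows PLINK's `--indep-pairwise 50 10 0.1`: 50-SNP windows
sliding by 10 within each chromosome; while any retained pair in a window
has squared Pearson dosage correlation (pairwise-complete) above 0.1, the
lower-MAF member of the worst pair is removed (tie: the later position).
The pass is single-shot, like PLINK's: survivors re-pack into new windows
only on a re-run, so a second pass over the output can remove further
sites. Within one window span the output is a true fixed point, and that
is the property the tests pin down. Exact PLINK bit-compatibility is not
promised (PLINK does not document its intra-window tie-breaking).

Fourfold-degenerate sites are taken from the reference + GFF3 CDS features
(phase-aware, minus strand by reverse complement): a position qualifies
when all four bases encode the same residue in the codon context, and a
position covered by several genes must qualify in every frame. Genes with
internal stop codons are skipped with a warning, codons containing
non-ACGT bases are skipped silently.

## Window scan

Windows are non-overlapping, 30 kb by default, half-open and 0-based
internally (1-based in reports), tiling each chromosome from its origin;
the trailing partial window is kept and flagged. Per-site kernels: π uses
the unbiased estimator 2j(n−j)/(n(n−1)); D_XY uses p₁(1−p₂) + p₂(1−p₁);
F_ST uses the Weir–Cockerham (1984) variance components with the window
estimate Σa / Σ(a+b+c) (ratio of sums). Tajima's D uses the standard
constants with n fixed at the population's full haploid sample size; sites
with more than 20% missing calls in the population are excluded from both
S and the π sum so that the fixed-n variance formula remains applicable.

Denominators matter and are explicit. π defaults to per-bp
(window length); D_XY defaults to per *variant site*, because the
early-diverged-window threshold of 0.35 is only meaningful on that scale —
a per-bp D_XY at realistic SNP densities is two orders of magnitude
smaller. Both statistics accept either denominator. W_early classification
is boundary-inclusive (D_XY ≥ 0.35).

The Mann–Whitney contrast uses midranks, tie-corrected variance and a
continuity correction; for samples of at most eight values each the
two-sided p comes from exact enumeration of all label assignments (doubled
smaller tail). The rare-allele sharing statistic counts sites whose global
minor-allele count over non-missing alleles lies in [2, 5] and reports the
fraction whose minor allele is seen at least once in each species; with no
rare sites the proportion is reported missing, not zero.

## McDonald–Kreitman stage

Within each gene's aligned, gap-free CDS haplotypes, a variable codon
position is a fixed difference when the two species share no allele there
and a polymorphism otherwise, with polymorphism pooled over both species.
Synonymy is judged by substituting the two alleles into the codon context
of the pooled within-gene consensus. Codons with more than one variable
position (or more than two alleles at a position) are skipped with a
warning — multi-hit codons cannot be classified unambiguously without
enumerating mutational paths, and the fixture generator never creates
them, so planted counts are recovered exactly. Genes whose consensus
contains a premature stop are skipped. Significance uses Fisher's exact
two-sided test on [[Pn, Ps], [Dn, Ds]] at α = 0.05, without
multiple-testing correction by default (an optional Benjamini–Hochberg
flag exists); NI and α are undefined when Ps, Dn or Ds is zero unless the
+0.5 pseudo-count option is enabled. Classification: significant with
NI < 1 → positive, significant with NI > 1 → negative, otherwise none
(undefined NI → undefined). Gene–window intersection requires at least one
CDS base pair inside an early window.

Haplotypes can be rebuilt from an unphased variant table by substituting
alleles into the reference CDS, each diploid contributing its two allele
columns as pseudo-haplotypes. True phase is unrecoverable, but the counts
are phase-robust under the one-variable-position-per-codon rule; multi-hit
codons, where phase would matter, are skipped anyway.

## Synthetic data and what it does (not) show

The generator emulates: two diploid populations under any
`DemographicModel`, loci tiled onto chromosomes with 1 kb spacing, clean
calls (DP ∈ [15, 45], GQ ∈ [40, 99]) before noise, and noise injection
that plants hard-filter violations on disjoint site subsets so the
surviving set is known by construction, not by running the filter. Coding
fixtures plant exact (Dn, Ds, Pn, Ps) counts, one event per codon, on
alternating strands. A companion builder embeds simulated variants in a
fourfold-degenerate codon background so the full
filter → prune → fourfold → SFS chain is exercised genuinely.

Not emulated: read-level errors and mapping artefacts, indels,
multiallelic sites, linked selection, recombination within loci, gene
conversion, and realistic gene structure (introns, UTRs, overlapping
ORFs). Green tests therefore certify the statistical machinery and its
bookkeeping — estimator formulas, filter semantics, scenario
identifiability under the model's own assumptions — not robustness to
real-data artefacts upstream of a VCF.

## Calibration experiments and problem sizes

The canned experiments (in `divflow.experiments`) use sizes chosen to
finish in minutes on one CPU while keeping Monte-Carlo error well below
the assertion margins: 5 000 loci for the panmictic-theory and
closed-form D_XY checks (3-standard-error bands); 1 500 replicates per
scenario for the simulator-vs-msprime comparison (95% CI overlap per SFS
cell); 2 000 simulations per scenario and 20 pseudo-observed datasets per
generator for ABC recovery; 150 windows for the neutral Tajima's D
calibration; 500 genes for the MKT false-positive rate. The neutral
false-positive check asserts the rate does not exceed the nominal 5%
beyond binomial noise: Fisher's exact test is conditionally conservative,
so rates of 2–4% are the expected behaviour, not a defect.

## Known limitations

- The coalescent engine is O(events) per genealogy in pure Python; it is
  sized for SFS-scale simulation (thousands of loci, tens of lineages),
  not chromosome-scale ancestry.
- Rejection ABC only; no regression adjustment or SMC. Acceptance shares
  depend on the chosen tolerance, and with weak data the gene-flow
  scenarios (which differ only in migration timing) remain mutually
  confusable — the summed gene-flow share is the robust quantity.
- PLINK pruning is reproduced in semantics, not bit-for-bit.
- Tajima's D with heavy, unevenly distributed missingness deviates from
  the fixed-n formula; the 20% per-site missingness cap bounds, but does
  not eliminate, this effect.
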