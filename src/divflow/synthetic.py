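"""Synthetic test fixtures with machine-readable ground truth.

Everything downstream of read mapping can be exercised on data this module
generates: diploid genotype tables simulated under a chosen divergence
scenario, noise injection that plants known hard-filter violations, and
coding-gene fixtures with exactly known synonymous/non-synonymous
polymorphism and divergence counts.  Each generator returns (or writes) a
:class:`FixtureTruth` sidecar recording what was planted, so tests can
assert exact recovery rather than plausibility.

In synthetic genotype tables the reference allele is the ancestral allele,
which makes unfolded site-frequency spectra exact; ``scramble_polarization``
mis-polarizes a chosen fraction of sites to exercise folding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import ceil, floor

import numpy as np

from .coalescent import DemographicModel, SimConfig, simulate_genealogy
from .variants import VariantTable

__all__ = [
    "NoiseConfig",
    "FixtureTruth",
    "genotypes_from_model",
    "reference_for",
    "inject_noise",
    "scramble_polarization",
    "make_coding_fixture",
    "CodingFixture",
]

DEFAULT_LAYOUT = [("chr1", 5_000_000), ("chr2", 5_000_000)]
LOCUS_SPACING = 1_000  # bp between consecutive simulated loci

_BASES = np.array(list("ACGT"))


@dataclass
class NoiseConfig:
    """Fractions of sites planted to violate each hard filter.

    Violations are applied to disjoint random site subsets so that the
    surviving set is unambiguous: a ``missing`` site gets >10% of its calls
    set to ``./.``; a ``bad_dp`` site gets all depths pushed below 10 or
    above 50; a ``low_gq`` site gets GQ < 30 on enough calls that GQ-masking
    alone breaks the missingness rule; a ``low_maf`` site has its genotypes
    rewritten to a single heterozygote (minor-allele frequency 1/2N < 0.1).
    """

    missing_site_frac: float = 0.0
    bad_dp_site_frac: float = 0.0
    low_gq_site_frac: float = 0.0
    low_maf_site_frac: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.missing_site_frac, self.bad_dp_site_frac,
                 self.low_gq_site_frac, self.low_maf_site_frac)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("noise fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("noise fractions must sum to at most 1")


@dataclass
class FixtureTruth:
    """Ground truth written next to every fixture; JSON round-trips."""

    model_label: str = "none"
    params: dict = field(default_factory=dict)
    seed: int | None = None
    surviving_sites: list = field(default_factory=list)  # (chrom, pos) pairs
    planted_violations: dict = field(default_factory=dict)
    mkt_counts: dict = field(default_factory=dict)  # gene -> [Dn, Ds, Pn, Ps]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FixtureTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["surviving_sites"] = [tuple(x) for x in d["surviving_sites"]]
        return cls(**d)


def _chrom_coords(n_loci: int, locus_length: int, layout):
    """Tile loci left-to-right across chromosomes; error on overflow."""
    coords = []
    li = 0
    for name, length in layout:
        offset = 0
        while li < n_loci and offset + locus_length <= length:
            coords.append((name, offset))
            offset += locus_length + LOCUS_SPACING
            li += 1
    if li < n_loci:
        raise ValueError(
            f"{n_loci} loci of {locus_length} bp do not fit in the layout"
        )
    return coords


def genotypes_from_model(
    model: DemographicModel,
    cfg: SimConfig,
    chrom_layout=None,
    rng: np.random.Generator | None = None,
) -> VariantTable:
    """Simulate a clean diploid genotype table under a divergence scenario.

    Haploid lineages ``2i, 2i+1`` of each deme are paired into diploid
    individual ``i``; loci are placed at non-overlapping coordinates with
    1 kb spacing and segregating sites get distinct positions within their
    locus.  Before any noise injection every call is confidently genotyped:
    DP uniform in [15, 45], GQ uniform in [40, 99].  The reference allele is
    ancestral.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    layout = chrom_layout or DEFAULT_LAYOUT
    coords = _chrom_coords(cfg.n_loci, cfg.locus_length, layout)
    n_ind = (cfg.n1 + cfg.n2) // 2
    ind_of_leaf = _leaf_to_individual(cfg.n1, cfg.n2)

    chroms, poss, refs, alts = [], [], [], []
    gts = []
    for chrom, offset in coords:
        g = simulate_genealogy(model, cfg.n1, cfg.n2, rng)
        lens = g.branch_lengths()
        counts = rng.poisson(lens * (cfg.mu * cfg.locus_length))
        n_mut = int(counts.sum())
        if n_mut == 0:
            continue
        if n_mut > cfg.locus_length:
            raise ValueError("more mutations than sites in a locus; lower mu")
        below = g.leaf_matrix()
        carriers = below[np.repeat(np.nonzero(counts)[0], counts[np.nonzero(counts)[0]])]
        pos_in_locus = np.sort(
            rng.choice(cfg.locus_length, size=n_mut, replace=False)
        )
        order = rng.permutation(n_mut)  # decouple position from branch order
        carriers = carriers[order]
        for k in range(n_mut):
            ref_b = _BASES[rng.integers(4)]
            alt_b = _BASES[(np.nonzero(_BASES == ref_b)[0][0] + 1 + rng.integers(3)) % 4]
            chroms.append(chrom)
            poss.append(offset + int(pos_in_locus[k]) + 1)  # 1-based
            refs.append(str(ref_b))
            alts.append(str(alt_b))
            gt = np.zeros((n_ind, 2), dtype=np.int8)
            leaves = np.nonzero(carriers[k])[0]
            gt[ind_of_leaf[leaves, 0], ind_of_leaf[leaves, 1]] = 1
            gts.append(gt)

    S = len(poss)
    gt_arr = (np.array(gts, dtype=np.int8).reshape(S, n_ind, 2)
              if S else np.zeros((0, n_ind, 2), dtype=np.int8))
    dp = rng.integers(15, 46, size=(S, n_ind)).astype(np.int32)
    gq = rng.integers(40, 100, size=(S, n_ind)).astype(np.int32)
    samples = [f"sp1_{i}" for i in range(cfg.n1 // 2)] + [
        f"sp2_{i}" for i in range(cfg.n2 // 2)
    ]
    pops = np.array(
        ["sp1"] * (cfg.n1 // 2) + ["sp2"] * (cfg.n2 // 2), dtype=object
    )
    return VariantTable(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        gt_arr, dp, gq, samples, pops,
    )


def _leaf_to_individual(n1: int, n2: int) -> np.ndarray:
    """Map haploid leaf index -> (diploid individual, allele slot)."""
    out = np.zeros((n1 + n2, 2), dtype=int)
    for leaf in range(n1):
        out[leaf] = (leaf // 2, leaf % 2)
    for leaf in range(n1, n1 + n2):
        j = leaf - n1
        out[leaf] = (n1 // 2 + j // 2, j % 2)
    return out


def reference_for(
    vt: VariantTable, chrom_layout=None, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Random reference sequences consistent with the table's ref alleles."""
    if rng is None:
        rng = np.random.default_rng(0)
    layout = chrom_layout or DEFAULT_LAYOUT
    ref = {}
    for name, length in layout:
        seq = rng.choice(_BASES, size=length)
        mask = vt.chrom == name
        seq[vt.pos[mask] - 1] = [r for r in vt.ref[mask]]
        ref[name] = "".join(seq)
    return ref


def scramble_polarization(
    vt: VariantTable, frac: float, rng: np.random.Generator
) -> VariantTable:
    """Swap ref/alt (mis-polarize) at a random fraction of sites."""
    out = vt.copy()
    flip = np.nonzero(rng.random(out.n_sites) < frac)[0]
    out.ref[flip], out.alt[flip] = out.alt[flip].copy(), out.ref[flip].copy()
    good = out.gt[flip] >= 0
    out.gt[flip] = np.where(good, 1 - out.gt[flip], out.gt[flip])
    return out


def inject_noise(
    vt: VariantTable, noise: NoiseConfig, rng: np.random.Generator
) -> tuple[VariantTable, FixtureTruth]:
    """Plant hard-filter violations at disjoint random site subsets.

    The truth sidecar lists exactly the sites that must survive the
    default hard filters: the untouched sites whose minor-allele frequency
    (known exactly from the clean genotypes) is at least 0.1.  Untouched
    sites already satisfy the depth, quality and missingness rules by
    construction of :func:`genotypes_from_model`.
    """
    out = vt.copy()
    S = out.n_sites
    n_ind = out.n_samples
    n_miss = round(noise.missing_site_frac * S)
    n_dp = round(noise.bad_dp_site_frac * S)
    n_gq = round(noise.low_gq_site_frac * S)
    n_maf = round(noise.low_maf_site_frac * S)
    if n_maf and 1.0 / (2 * n_ind) >= 0.1:
        raise ValueError("too few samples for a singleton to fall below MAF 0.1")
    perm = rng.permutation(S)
    pick_miss = perm[:n_miss]
    pick_dp = perm[n_miss:n_miss + n_dp]
    pick_gq = perm[n_miss + n_dp:n_miss + n_dp + n_gq]
    pick_maf = perm[n_miss + n_dp + n_gq:n_miss + n_dp + n_gq + n_maf]

    n_break = ceil(0.10 * n_ind) + 1  # calls needed to break the 10% rule
    n_break = min(n_break, n_ind)
    for s in pick_miss:
        cols = rng.choice(n_ind, size=n_break, replace=False)
        out.gt[s, cols] = -1
    for i, s in enumerate(pick_dp):
        if i % 2 == 0:
            out.dp[s] = rng.integers(1, 9, size=n_ind)
        else:
            out.dp[s] = rng.integers(55, 90, size=n_ind)
    for s in pick_gq:
        cols = rng.choice(n_ind, size=n_break, replace=False)
        out.gq[s, cols] = rng.integers(0, 30, size=n_break)
    for s in pick_maf:
        out.gt[s] = 0
        het = rng.integers(n_ind)
        out.gt[s, het, rng.integers(2)] = 1

    touched = np.zeros(S, dtype=bool)
    touched[np.concatenate([pick_miss, pick_dp, pick_gq, pick_maf])
            if S else []] = True
    maf = vt.maf()  # exact, from the clean table
    survive = ~touched & (maf >= 0.1)
    truth = FixtureTruth(
        surviving_sites=[
            (str(vt.chrom[i]), int(vt.pos[i])) for i in np.nonzero(survive)[0]
        ],
        planted_violations={
            "missing": int(n_miss),
            "bad_dp": int(n_dp),
            "low_gq": int(n_gq),
            "low_maf_planted": int(n_maf),
            "low_maf_natural": int((~touched & (maf < 0.1)).sum()),
        },
    )
    return out, truth


def fourfold_reference_for(
    vt: VariantTable,
    cfg: SimConfig,
    chrom_layout=None,
    rng: np.random.Generator | None = None,
):
    """Reference + annotation placing the table's variants in coding context.

    Chromosomes are tiled with codons whose first two bases come from
    fourfold-degenerate families (GGN, GCN, ...), so every third codon
    position is fourfold degenerate and no stop codon can arise from the
    invariant background.  Reference alleles of the variant table are
    written in place; when a variant falls on a codon's first or second
    position the codon's other prefix base is set to ``C`` so the reference
    stays stop-free.  Each simulated locus becomes one frame-aligned,
    plus-strand, single-CDS gene.

    Returns ``(ref, gff_rows)`` for :func:`divflow.io.write_fasta` /
    :func:`divflow.io.write_gff3`.  Variants at third positions of the
    background codons — about one third of all simulated sites — survive a
    fourfold-degenerate restriction.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    layout = chrom_layout or DEFAULT_LAYOUT
    coords = _chrom_coords(cfg.n_loci, cfg.locus_length, layout)
    prefixes = np.array(_FOURFOLD_PREFIXES)
    ref: dict[str, str] = {}
    gff_rows = []
    gi = 0
    for name, length in layout:
        n_codons = length // 3
        codons = np.char.add(
            prefixes[rng.integers(len(prefixes), size=n_codons)],
            _BASES[rng.integers(4, size=n_codons)],
        )
        seq = list("".join(codons).ljust(length, "A"))
        mask = vt.chrom == name
        by_codon: dict[int, list[int]] = {}
        for p in vt.pos[mask]:
            by_codon.setdefault((int(p) - 1) // 3, []).append(int(p) - 1)
        for ci, hits in by_codon.items():
            offsets = {h % 3 for h in hits}
            if offsets - {2}:  # a prefix position is variant
                for off in (0, 1):
                    if 3 * ci + off not in hits:
                        seq[3 * ci + off] = "C"
        refs = {int(p) - 1: str(r) for p, r in zip(vt.pos[mask], vt.ref[mask])}
        for p0, r in refs.items():
            seq[p0] = r
        ref[name] = "".join(seq)
        for chrom, offset in coords:
            if chrom != name:
                continue
            start0 = -(-offset // 3) * 3  # frame-aligned, 0-based
            span = offset + cfg.locus_length - start0
            end0 = start0 + 3 * (span // 3)
            if end0 - start0 < 3:
                continue
            gid = f"locus{gi:04d}"
            gi += 1
            gff_rows.append((name, "divflow", "gene", start0 + 1, end0, ".",
                             "+", ".", f"ID={gid}"))
            gff_rows.append((name, "divflow", "CDS", start0 + 1, end0, ".",
                             "+", "0", f"ID={gid}.cds;Parent={gid}"))
    return ref, gff_rows


# ---- coding-gene fixtures for the MKT stage ---------------------------

# fourfold codon families (prefix -> residue is constant over the 3rd base)
_FOURFOLD_PREFIXES = ["GG", "GC", "CC", "AC", "GT", "CT", "TC", "CG"]
_FILLER = "GCC"  # Ala, no planted variation

# (codon_A, codon_B) pairs differing at one position, non-synonymous
_NONSYN_PAIRS = [("AAA", "GAA"), ("TTT", "GTT"), ("ATT", "ACT"), ("AGA", "AGC")]
# synonymous pairs: third-position swap inside a fourfold family
_SYN_PAIRS = [(p + "A", p + "T") for p in _FOURFOLD_PREFIXES]


@dataclass
class CodingFixture:
    """Reference + annotation + per-gene haplotype alignments + truth."""

    ref: dict[str, str]
    gff3: list  # rows for io.write_gff3
    alignments: dict  # gene -> {"sp1": [haplotypes], "sp2": [haplotypes]}
    gene_coords: dict  # gene -> (chrom, strand, start, end) 1-based inclusive
    truth: FixtureTruth


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(s))


def make_coding_fixture(
    per_gene_counts,
    n_haplotypes: int = 4,
    rng: np.random.Generator | None = None,
    chrom: str = "chrG",
    intergenic: int = 200,
) -> CodingFixture:
    """Build coding genes with exactly planted MKT counts.

    ``per_gene_counts`` is a list of ``(Dn, Ds, Pn, Ps)`` tuples, one per
    gene.  Every planted event occupies its own codon (codons never carry
    two variable positions): fixed differences separate the two species'
    haplotypes at one codon position; polymorphisms put the alternative
    allele on exactly one haplotype of one (randomly chosen) species, so
    the within-gene consensus is always the major allele.  Genes alternate
    between the + and - strand; species 1's consensus is the reference.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ref_seq: list[str] = []
    gff_rows = []
    alignments: dict[str, dict[str, list[str]]] = {}
    gene_coords: dict[str, tuple] = {}
    truth_counts: dict[str, list[int]] = {}
    cursor = 0  # 0-based offset into the chromosome being built

    for gi, (dn, ds, pn, ps) in enumerate(per_gene_counts):
        gid = f"gene{gi:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        codons_a: list[str] = ["ATG"]  # species-1 haplotype codons
        events: list[tuple] = []  # (codon index, kind, alt codon, which sp)
        for kind, k in (("Dn", dn), ("Ds", ds), ("Pn", pn), ("Ps", ps)):
            for _ in range(k):
                if kind in ("Dn", "Pn"):
                    ca, cb = _NONSYN_PAIRS[int(rng.integers(len(_NONSYN_PAIRS)))]
                else:
                    ca, cb = _SYN_PAIRS[int(rng.integers(len(_SYN_PAIRS)))]
                sp = 1 if kind in ("Dn", "Ds") else int(rng.integers(2))
                events.append((len(codons_a), kind, cb, sp))
                codons_a.append(ca)
        codons_a.append(_FILLER)  # at least one invariant codon
        codons_a.append("TAA")

        hap_a = ["".join(codons_a) for _ in range(n_haplotypes)]
        codons_b = list(codons_a)
        for ci, kind, alt_codon, sp in events:
            if kind in ("Dn", "Ds"):  # fixed difference: all of species 2
                codons_b[ci] = alt_codon
        hap_b = ["".join(codons_b) for _ in range(n_haplotypes)]
        for ci, kind, alt_codon, sp in events:
            if kind in ("Pn", "Ps"):  # polymorphism: one haplotype
                target = hap_a if sp == 0 else hap_b
                h = list(target[0])
                h[3 * ci:3 * ci + 3] = alt_codon
                target[0] = "".join(h)

        cds = hap_a[1]  # an invariant species-1 haplotype == consensus
        gene_seq = cds if strand == "+" else _revcomp(cds)
        spacer = "".join(rng.choice(_BASES, size=intergenic))
        ref_seq.append(spacer)
        cursor += intergenic
        start = cursor + 1  # 1-based
        end = cursor + len(gene_seq)
        ref_seq.append(gene_seq)
        cursor = end

        gff_rows.append((chrom, "divflow", "gene", start, end, ".", strand,
                         ".", f"ID={gid}"))
        gff_rows.append((chrom, "divflow", "mRNA", start, end, ".", strand,
                         ".", f"ID={gid}.t1;Parent={gid}"))
        gff_rows.append((chrom, "divflow", "CDS", start, end, ".", strand,
                         "0", f"ID={gid}.cds;Parent={gid}.t1"))
        alignments[gid] = {"sp1": hap_a, "sp2": hap_b}
        gene_coords[gid] = (chrom, strand, start, end)
        truth_counts[gid] = [dn, ds, pn, ps]

    truth = FixtureTruth(mkt_counts=truth_counts)
    return CodingFixture(
        ref={chrom: "".join(ref_seq)},
        gff3=gff_rows,
        alignments=alignments,
        gene_coords=gene_coords,
        truth=truth,
    )
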