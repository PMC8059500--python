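"""Variant tables: VCF IO, hard site filters, LD pruning, fourfold sites.

The in-memory container is :class:`VariantTable`: biallelic SNPs x diploid
samples with per-call genotype, read depth (DP) and genotype quality (GQ),
plus a sample -> population map.  Coordinates are 1-based in the VCF/GFF3
domain (as stored here) and converted to half-open 0-based only inside
window arithmetic.

The hard site filters reproduce a common resequencing cleanup: mask
low-confidence calls (GQ < 30), then drop sites with more than 10% missing
calls, mean depth per individual outside [10, 50], or minor-allele
frequency below 0.10.  LD pruning follows the PLINK
``--indep-pairwise 50 10 0.1`` scheme on genotype dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VariantTable",
    "SiteFilterConfig",
    "filter_sites",
    "ld_prune",
    "fourfold_degenerate_sites",
    "subset_sites",
    "subset_samples",
    "read_vcf",
    "write_vcf",
]

MISSING = -1  # allele code for a missing call


@dataclass
class VariantTable:
    """Biallelic sites x diploid samples.

    Attributes
    ----------
    chrom, pos, ref, alt : arrays of shape (S,)
        Site coordinates (``pos`` 1-based) and alleles.
    gt : int8 array of shape (S, N, 2)
        Allele codes 0 (ref), 1 (alt); -1 for a missing call (both alleles
        of a call are always set missing together).
    dp, gq : int32 arrays of shape (S, N)
        Per-call read depth and phred genotype quality.
    samples : list of sample identifiers.
    pops : array of shape (N,) of population labels (e.g. 'sp1'/'sp2').
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    samples: list[str]
    pops: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        if self.pops is None:
            self.pops = np.array(["sp1"] * len(self.samples), dtype=object)
        self.pops = np.asarray(self.pops, dtype=object)
        if self.gt.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError("gt must have shape (sites, samples, 2)")
        if len(self.pops) != self.n_samples:
            raise ValueError("every sample needs a population label")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    # ---- basic properties --------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pop_index(self, label: str) -> np.ndarray:
        idx = np.nonzero(self.pops == label)[0]
        if idx.size == 0:
            raise KeyError(f"no samples in population {label!r}")
        return idx

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pops:
            if p not in seen:
                seen.append(p)
        return seen

    def call_missing(self) -> np.ndarray:
        """(S, N) boolean: diploid call is missing."""
        return (self.gt < 0).any(axis=2)

    def dosage(self) -> np.ndarray:
        """(S, N) float alt-allele dosage {0,1,2}; NaN where missing."""
        d = self.gt.sum(axis=2).astype(float)
        d[self.call_missing()] = np.nan
        return d

    def allele_counts(self, sample_idx=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt count, non-missing allele total) over given samples."""
        gt = self.gt if sample_idx is None else self.gt[:, sample_idx, :]
        good = gt >= 0
        return (gt == 1).sum(axis=(1, 2)), good.sum(axis=(1, 2))

    def maf(self) -> np.ndarray:
        """Minor-allele frequency over non-missing alleles; NaN if no calls."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def copy(self) -> "VariantTable":
        return VariantTable(
            self.chrom.copy(), self.pos.copy(), self.ref.copy(),
            self.alt.copy(), self.gt.copy(), self.dp.copy(), self.gq.copy(),
            list(self.samples), self.pops.copy(),
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Hard-filter thresholds (defaults follow the standard cleanup)."""

    max_missing_frac: float = 0.10
    min_mean_dp: float = 10.0
    max_mean_dp: float = 50.0
    min_gq: int = 30
    min_maf: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must lie in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


def filter_sites(
    vt: VariantTable,
    cfg: SiteFilterConfig = SiteFilterConfig(),
    return_mask: bool = False,
):
    """Apply the hard site filters; returns the surviving table.

    Order of operations (fixed): (1) mask calls with GQ below ``min_gq`` to
    missing; (2) drop sites whose missing-call fraction exceeds
    ``max_missing_frac``; (3) drop sites whose mean DP over non-missing
    calls falls outside ``[min_mean_dp, max_mean_dp]``; (4) drop sites whose
    minor-allele frequency over non-missing alleles is below ``min_maf``.
    Masking precedes the site-level tests, so a GQ-masked call counts as
    missing for the missingness, depth and frequency rules.
    """
    if vt.n_samples == 0:
        raise ValueError("variant table has no samples")
    out = vt.copy()
    low_gq = out.gq < cfg.min_gq
    out.gt[low_gq] = MISSING

    miss = out.call_missing()
    miss_frac = miss.mean(axis=1) if out.n_samples else np.zeros(out.n_sites)
    ok_miss = miss_frac <= cfg.max_missing_frac

    n_called = (~miss).sum(axis=1)
    dp_sum = np.where(miss, 0, out.dp).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_dp = np.where(n_called > 0, dp_sum / np.maximum(n_called, 1), np.nan)
    ok_dp = (mean_dp >= cfg.min_mean_dp) & (mean_dp <= cfg.max_mean_dp)

    maf = out.maf()
    ok_maf = maf >= cfg.min_maf

    keep = ok_miss & np.nan_to_num(ok_dp) & np.nan_to_num(ok_maf)
    filtered = subset_sites(out, np.nonzero(keep)[0])
    if return_mask:
        return filtered, keep
    return filtered


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    m = np.ma.masked_invalid(dos)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> masked entries
        r = np.ma.corrcoef(m)
    r2 = np.asarray(r.filled(0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    vt: VariantTable,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """PLINK-style ``--indep-pairwise`` pruning; returns kept site indices.

    Per chromosome, windows of ``window_snps`` consecutive SNPs slide by
    ``step_snps``.  Within a window, while any retained pair has squared
    dosage correlation above ``r2_max``, the member of the worst
    (highest-r2) pair with the lower minor-allele frequency is removed
    (tie: the later position goes).  A site removed in any window stays
    removed.  Correlations use pairwise-complete observations.
    """
    dosage = vt.dosage()
    maf = vt.maf()
    removed = np.zeros(vt.n_sites, dtype=bool)
    for c in _unique_in_order(vt.chrom):
        sites = np.nonzero(vt.chrom == c)[0]
        for start in range(0, len(sites), step_snps):
            win = sites[start:start + window_snps]
            live = win[~removed[win]]
            if live.size < 2:
                if start + window_snps >= len(sites):
                    break
                continue
            r2 = _pairwise_r2(dosage[live])
            while True:
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                a, b = live[i], live[j]
                # drop the lower-MAF member; tie -> the later position
                if (maf[a], -vt.pos[a]) <= (maf[b], -vt.pos[b]):
                    drop, di = a, i
                else:
                    drop, dj = b, j
                    di = dj
                removed[drop] = True
                r2[di, :] = 0.0
                r2[:, di] = 0.0
            if start + window_snps >= len(sites):
                break
    return np.nonzero(~removed)[0]


def subset_sites(vt: VariantTable, idx) -> VariantTable:
    """Subset to the given site indices (or boolean mask), order-preserving."""
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.nonzero(idx)[0]
    return VariantTable(
        vt.chrom[idx], vt.pos[idx], vt.ref[idx], vt.alt[idx],
        vt.gt[idx], vt.dp[idx], vt.gq[idx], list(vt.samples), vt.pops.copy(),
    )


def subset_samples(vt: VariantTable, ids: list[str]) -> VariantTable:
    """Subset to the named samples, in the order given."""
    lookup = {s: i for i, s in enumerate(vt.samples)}
    try:
        cols = np.array([lookup[s] for s in ids], dtype=int)
    except KeyError as e:
        raise KeyError(f"unknown sample id {e.args[0]!r}") from None
    return VariantTable(
        vt.chrom.copy(), vt.pos.copy(), vt.ref.copy(), vt.alt.copy(),
        vt.gt[:, cols, :], vt.dp[:, cols], vt.gq[:, cols],
        list(ids), vt.pops[cols],
    )


def _unique_in_order(arr) -> list:
    seen: list = []
    for x in arr:
        if x not in seen:
            seen.append(x)
    return seen


# ---- fourfold-degenerate site extraction ------------------------------

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _codon_tables():
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[1]
    trans = dict(tab.forward_table)
    for stop in tab.stop_codons:
        trans[stop] = "*"
    return trans

_TRANSLATE = _codon_tables()


def _is_fourfold(codon: str, offset: int) -> bool:
    """All four bases at ``offset`` of ``codon`` encode the same residue."""
    aas = {
        _TRANSLATE[codon[:offset] + b + codon[offset + 1:]] for b in _BASES
    }
    return len(aas) == 1 and "*" not in aas


def cds_layout(gff3_path):
    """Collect GFF3 CDS features grouped by parent gene/transcript.

    Returns ``{gene_id: (chrom, strand, phase, [(start, end), ...])}`` with
    1-based inclusive segment coordinates sorted by position and the phase
    of the first segment in translation order.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [])
        gid = parents[0] if parents else (feat.id or f"cds_{len(genes)}")
        rec = genes.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand, "segs": []}
        )
        phase = 0 if feat.frame in (None, ".") else int(feat.frame)
        rec["segs"].append((feat.start, feat.end, phase))
    out = {}
    for gid, rec in genes.items():
        segs = sorted(rec["segs"])
        first = segs[-1] if rec["strand"] == "-" else segs[0]
        out[gid] = (
            rec["chrom"], rec["strand"], first[2],
            [(s, e) for s, e, _ in segs],
        )
    return out


def fourfold_degenerate_sites(ref, gff3_path) -> dict[str, np.ndarray]:
    """Genomic positions (1-based) that are fourfold degenerate in every
    covering reading frame.

    ``ref`` maps chromosome name to its sequence string (see
    :func:`divflow.io.read_fasta`).  Minus-strand CDS are handled by reverse
    complement; a position covered by CDS of several genes is returned only
    if fourfold in each.  Genes whose CDS contains an internal stop are
    skipped with a warning; codons containing non-ACGT bases are skipped.
    """
    verdicts: dict[str, dict[int, bool]] = {}
    for gid, (chrom, strand, phase, segs) in cds_layout(gff3_path).items():
        if chrom not in ref:
            warnings.warn(f"gene {gid}: chromosome {chrom!r} not in reference")
            continue
        seq = ref[chrom]
        positions: list[int] = []
        for s, e in segs:
            positions.extend(range(s, e + 1))
        bases = [seq[p - 1].upper() for p in positions]
        if strand == "-":
            positions.reverse()
            bases = [_COMP.get(b, "N") for b in reversed(bases)]
        positions = positions[phase:]
        bases = bases[phase:]
        n_codons = len(positions) // 3
        gene_verdicts: list[tuple[int, bool]] = []
        skip = False
        for ci in range(n_codons):
            codon = "".join(bases[3 * ci:3 * ci + 3])
            if any(b not in _BASES for b in codon):
                continue
            if _TRANSLATE[codon] == "*" and ci < n_codons - 1:
                warnings.warn(f"gene {gid}: internal stop codon; skipped")
                skip = True
                break
            for off in range(3):
                gene_verdicts.append(
                    (positions[3 * ci + off], _is_fourfold(codon, off))
                )
        if skip:
            continue
        chrom_v = verdicts.setdefault(chrom, {})
        for p, ok in gene_verdicts:
            chrom_v[p] = chrom_v.get(p, True) and ok
    return {
        c: np.array(sorted(p for p, ok in v.items() if ok), dtype=np.int64)
        for c, v in verdicts.items()
    }


# ---- VCF IO -----------------------------------------------------------

def write_vcf(vt: VariantTable, path, contigs: dict[str, int] | None = None) -> None:
    """Write as VCF 4.2 with GT:DP:GQ calls (``./.`` for missing)."""
    lines = ["##fileformat=VCFv4.2", "##source=divflow"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in _unique_in_order(vt.chrom):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(vt.samples),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for s in range(vt.n_sites):
            calls = []
            for i in range(vt.n_samples):
                a, b = vt.gt[s, i]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                calls.append(f"{gt}:{vt.dp[s, i]}:{vt.gq[s, i]}")
            fh.write(
                f"{vt.chrom[s]}\t{vt.pos[s]}\t.\t{vt.ref[s]}\t{vt.alt[s]}"
                f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path, pop_map: dict[str, str] | None = None) -> VariantTable:
    """Read a (plain or bgzipped) VCF into a :class:`VariantTable`.

    Multiallelic and non-SNP records are skipped.  ``pop_map`` assigns a
    population label per sample; unmapped samples get ``'sp1'``.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chrom, pos, ref, alt = [], [], [], []
        gts, dps, gqs = [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            g = np.full((len(samples), 2), MISSING, dtype=np.int8)
            d = np.zeros(len(samples), dtype=np.int32)
            q = np.zeros(len(samples), dtype=np.int32)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                al = call.get("GT", (None, None))
                if al is not None and len(al) == 2 and None not in al:
                    g[i] = al
                d[i] = call.get("DP") or 0
                q[i] = call.get("GQ") or 0
            gts.append(g)
            dps.append(d)
            gqs.append(q)
    n = len(pos)
    pops = np.array(
        [(pop_map or {}).get(s, "sp1") for s in samples], dtype=object
    )
    return VariantTable(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object), np.array(alt, dtype=object),
        np.array(gts, dtype=np.int8).reshape(n, len(samples), 2),
        np.array(dps, dtype=np.int32).reshape(n, len(samples)),
        np.array(gqs, dtype=np.int32).reshape(n, len(samples)),
        samples, pops,
    )
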