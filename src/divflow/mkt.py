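"""Per-gene McDonald-Kreitman tests and intersection with early windows.

The McDonald-Kreitman contrast compares, within each gene's coding
sequence, non-synonymous vs synonymous counts between fixed interspecific
differences (Dn, Ds) and intraspecific polymorphisms (Pn, Ps).  Under
neutrality Pn/Ps = Dn/Ds; an excess of non-synonymous divergence
(neutrality index NI = (Pn/Ps)/(Dn/Ds) < 1, alpha = 1 - NI > 0) with a
significant Fisher exact test marks positive selection, NI > 1 marks
segregating weakly deleterious variation (negative selection).

Counting scheme: a variable codon position is a fixed difference when the
two species share no allele there, and a polymorphism otherwise (pooled
over both species); codons with more than one variable position are
skipped.  Haplotypes can come from pre-built per-gene alignments or be
reconstructed from a variant table plus reference and annotation, with the
two alleles of an unphased heterozygote contributing two pseudo-haplotypes
(phase-robust under the one-variable-position-per-codon rule).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .variants import _COMP, _TRANSLATE, VariantTable, cds_layout

__all__ = [
    "GeneAlignment",
    "MKTable",
    "count_mkt",
    "fisher_2x2",
    "neutrality_index",
    "classify_selection",
    "mkt_scan",
    "gene_alignments_from_table",
    "genes_in_early_windows",
]


@dataclass
class GeneAlignment:
    """Aligned, gap-free CDS haplotypes of one gene for two species."""

    gene_id: str
    haplotypes: dict  # species label -> list of CDS strings
    chrom: str | None = None
    strand: str = "+"
    segments: tuple = ()  # CDS segments, 1-based inclusive

    def __post_init__(self) -> None:
        lengths = {
            len(h) for haps in self.haplotypes.values() for h in haps
        }
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: haplotype lengths differ")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")


@dataclass
class MKTable:
    gene: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    p_fisher: float = float("nan")
    NI: float = float("nan")
    alpha: float = float("nan")
    sel_class: str = "undefined"


class PrematureStopError(ValueError):
    pass


def _consensus(haps: list[str]) -> str:
    cols = zip(*haps)
    return "".join(Counter(col).most_common(1)[0][0] for col in cols)


def count_mkt(g: GeneAlignment) -> tuple[int, int, int, int]:
    """Count (Dn, Ds, Pn, Ps) over the gene's variable codon positions.

    Changes are classified as synonymous/non-synonymous by substituting the
    two alleles into the codon context of the pooled within-gene consensus.
    Codons with more than one variable position, or with more than two
    alleles at a position, are skipped with a warning.  A premature stop in
    the consensus raises :class:`PrematureStopError`.
    """
    species = list(g.haplotypes)
    if len(species) != 2:
        raise ValueError("exactly two species are required")
    for sp in species:
        if len(g.haplotypes[sp]) < 2:
            raise ValueError(f"{g.gene_id}: need >= 2 haplotypes in {sp}")
    all_haps = g.haplotypes[species[0]] + g.haplotypes[species[1]]
    L = len(all_haps[0])
    cons = _consensus(all_haps)
    n_codons = L // 3
    for ci in range(n_codons - 1):
        if _TRANSLATE.get(cons[3 * ci:3 * ci + 3]) == "*":
            raise PrematureStopError(
                f"{g.gene_id}: premature stop codon in consensus"
            )

    dn = ds = pn = ps = 0
    for ci in range(n_codons):
        sl = slice(3 * ci, 3 * ci + 3)
        codons = [h[sl] for h in all_haps]
        var_offsets = [
            off for off in range(3)
            if len({c[off] for c in codons}) > 1
        ]
        if not var_offsets:
            continue
        if len(var_offsets) > 1:
            warnings.warn(
                f"{g.gene_id}: codon {ci} has multiple variable positions; skipped"
            )
            continue
        off = var_offsets[0]
        alleles_1 = {h[sl][off] for h in g.haplotypes[species[0]]}
        alleles_2 = {h[sl][off] for h in g.haplotypes[species[1]]}
        alleles = alleles_1 | alleles_2
        if len(alleles) > 2:
            warnings.warn(
                f"{g.gene_id}: codon {ci} carries >2 alleles; skipped"
            )
            continue
        b1, b2 = sorted(alleles)
        ctx = cons[sl]
        aa1 = _TRANSLATE.get(ctx[:off] + b1 + ctx[off + 1:])
        aa2 = _TRANSLATE.get(ctx[:off] + b2 + ctx[off + 1:])
        if aa1 is None or aa2 is None:
            continue
        synonymous = aa1 == aa2
        fixed = len(alleles_1 & alleles_2) == 0
        if fixed:
            dn, ds = dn + (not synonymous), ds + synonymous
        else:
            pn, ps = pn + (not synonymous), ps + synonymous
    return int(dn), int(ds), int(pn), int(ps)


def fisher_2x2(Dn: int, Ds: int, Pn: int, Ps: int) -> float:
    """Two-sided Fisher exact p for the 2x2 polymorphism/divergence table."""
    if min(Dn, Ds, Pn, Ps) < 0:
        raise ValueError("counts must be non-negative")
    if Dn + Ds + Pn + Ps == 0:
        return 1.0
    return float(fisher_exact([[Pn, Ps], [Dn, Ds]], alternative="two-sided")[1])


def neutrality_index(
    Dn: int, Ds: int, Pn: int, Ps: int, pseudocount: bool = False
) -> tuple[float, float]:
    """Neutrality index NI = (Pn/Ps)/(Dn/Ds) and alpha = 1 - NI.

    Undefined (NaN) whenever Ps, Dn or Ds is zero, unless ``pseudocount``
    adds 0.5 to every cell first.
    """
    if pseudocount:
        Dn, Ds, Pn, Ps = (x + 0.5 for x in (Dn, Ds, Pn, Ps))
    if Ps == 0 or Dn == 0 or Ds == 0:
        return float("nan"), float("nan")
    ni = (Pn / Ps) / (Dn / Ds)
    return float(ni), float(1.0 - ni)


def classify_selection(
    p_fisher: float, NI: float, alpha_level: float = 0.05
) -> str:
    """'positive' (significant, NI < 1), 'negative' (significant, NI > 1),
    'none' otherwise; 'undefined' when NI is undefined."""
    if np.isnan(NI):
        return "undefined"
    if p_fisher < alpha_level:
        if NI < 1:
            return "positive"
        if NI > 1:
            return "negative"
    return "none"


def mkt_scan(
    alignments,
    alpha_level: float = 0.05,
    pseudocount: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the MKT over gene alignments; one row per analysable gene.

    ``alignments`` is an iterable of :class:`GeneAlignment`.  Genes with a
    premature stop in their consensus are skipped with a warning.  With
    ``fdr`` the classification uses Benjamini-Hochberg adjusted p-values
    (raw p is reported either way).
    """
    rows = []
    for g in alignments:
        try:
            dn, ds, pn, ps = count_mkt(g)
        except PrematureStopError as e:
            warnings.warn(str(e))
            continue
        p = fisher_2x2(dn, ds, pn, ps)
        ni, alpha = neutrality_index(dn, ds, pn, ps, pseudocount)
        rows.append(MKTable(g.gene_id, dn, ds, pn, ps, p, ni, alpha))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df) == 0:
        return df
    p_for_class = df["p_fisher"].to_numpy()
    if fdr:
        p_for_class = _bh_adjust(p_for_class)
        df["p_adjusted"] = p_for_class
    df["sel_class"] = [
        classify_selection(p, ni, alpha_level)
        for p, ni in zip(p_for_class, df["NI"])
    ]
    return df


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def gene_alignments_from_table(
    vt: VariantTable, ref: dict[str, str], gff3_path
) -> list[GeneAlignment]:
    """Reconstruct per-gene CDS haplotypes by substituting VCF alleles into
    the reference CDS.

    Each diploid sample contributes its two allele columns as two
    pseudo-haplotypes (unphased; see module docstring).  Species labels are
    taken from the table's population labels.
    """
    out = []
    species = vt.populations
    pos_lookup: dict[str, dict[int, int]] = {}
    for c in dict.fromkeys(vt.chrom):
        mask = vt.chrom == c
        pos_lookup[c] = {
            int(p): i for p, i in zip(vt.pos[mask], np.nonzero(mask)[0])
        }
    for gid, (chrom, strand, phase, segs) in cds_layout(gff3_path).items():
        if chrom not in ref:
            continue
        positions: list[int] = []
        for s, e in segs:
            positions.extend(range(s, e + 1))
        if strand == "-":
            positions.reverse()
        positions = positions[phase:]
        positions = positions[: 3 * (len(positions) // 3)]
        refseq = ref[chrom]
        base_ref = [
            refseq[p - 1].upper() if strand == "+"
            else _COMP.get(refseq[p - 1].upper(), "N")
            for p in positions
        ]
        haps: dict[str, list[str]] = {sp: [] for sp in species}
        lookup = pos_lookup.get(chrom, {})
        hits = [(k, lookup[p]) for k, p in enumerate(positions) if p in lookup]
        for si, sample in enumerate(vt.samples):
            sp = vt.pops[si]
            for slot in range(2):
                h = list(base_ref)
                for k, row in hits:
                    allele = vt.gt[row, si, slot]
                    if allele == 1:
                        alt = vt.alt[row]
                        h[k] = alt if strand == "+" else _COMP.get(alt, "N")
                    # missing alleles fall back to the reference base
                haps[sp].append("".join(h))
        out.append(GeneAlignment(gid, haps, chrom, strand, tuple(segs)))
    return out


def genes_in_early_windows(
    mkt_df: pd.DataFrame,
    gene_coords: dict,
    early_windows,
) -> list[str]:
    """Positively selected genes whose CDS overlaps any early window.

    ``gene_coords`` maps gene id to ``(chrom, strand, start, end)`` or
    ``(chrom, strand, [(start, end), ...])`` with 1-based inclusive
    coordinates; ``early_windows`` is an iterable of ``(chrom, start, end)``
    half-open 0-based intervals (e.g. the early rows of a scan).  A single
    overlapping base pair suffices.
    """
    wins: dict[str, list[tuple[int, int]]] = {}
    if isinstance(early_windows, pd.DataFrame):
        sub = early_windows
        if "early" in sub.columns:
            sub = sub[sub["early"].fillna(False)]
        early_windows = list(
            zip(sub["chrom"], sub["start"], sub["end"])
        )
    for c, s, e in early_windows:
        wins.setdefault(c, []).append((int(s), int(e)))

    selected = set(
        mkt_df.loc[mkt_df["sel_class"] == "positive", "gene"]
    )
    hits = []
    for gid in mkt_df["gene"]:
        if gid not in selected or gid not in gene_coords:
            continue
        coords = gene_coords[gid]
        chrom, third = coords[0], coords[2]
        segs = list(third) if isinstance(third, (list, tuple)) \
            else [(coords[2], coords[3])]
        for s, e in segs:
            s0, e0 = int(s) - 1, int(e)  # to half-open 0-based
            if any(s0 < we and ws < e0 for ws, we in wins.get(chrom, [])):
                hits.append(gid)
                break
    return hits
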