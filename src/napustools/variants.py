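"""VCF genotype loading and SNP effect classification.

Genotypes are read into a site x haplotype matrix (biallelic SNPs only,
sites above the missing-rate ceiling dropped), which is the container the
windowed diversity / differentiation scan consumes.  Effect classification
places each SNP relative to a GFF3 gene annotation: a record per
overlapping gene (exon/intron and, inside CDS, a codon-level
missense/synonymous/stop call), strand-aware upstream/downstream flanks,
and a single intergenic record otherwise — so one SNP can carry several
annotations and category counts are over records, not SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CATEGORIES = ("exon", "intron", "upstream", "downstream", "intergenic")
SUBTYPES = ("missense", "synonymous", "stop_gained", "stop_lost", "none")

__all__ = [
    "GenotypeMatrix",
    "EffectRecord",
    "load_genotypes",
    "read_group_map",
    "classify_snp_effects",
    "summarize_effects",
    "effect_percentages",
    "percent_of",
]


class GroupMapError(ValueError):
    """A VCF sample has no group assignment."""


class VCFFormatError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x haploid allele calls.

    ``calls`` is int8, shape (n_sites, 2*n_samples); -1 marks a missing
    haploid call.  ``sample_groups`` maps sample id -> group label.
    """

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    samples: list[str]
    sample_groups: dict[str, str]
    missing_frac: np.ndarray = field(default=None)  # per retained site
    filter_log: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def group_columns(self, group: str) -> np.ndarray:
        """Haplotype column indices belonging to one group."""
        idx = [i for i, s in enumerate(self.samples) if self.sample_groups[s] == group]
        if not idx:
            raise GroupMapError(f"group {group!r} has no samples")
        cols = np.asarray(idx)
        return np.sort(np.concatenate([2 * cols, 2 * cols + 1]))


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, group label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def load_genotypes(
    vcf_path: str | Path,
    group_map: dict[str, str] | str | Path,
    max_missing: float = 0.25,
) -> GenotypeMatrix:
    """Load biallelic SNP genotypes, dropping high-missingness sites.

    Sites with more than two alleles, non-SNP alleles, or a missing-call
    fraction above ``max_missing`` are dropped; drop counts are recorded in
    ``filter_log`` and logged.
    """
    if not isinstance(group_map, dict):
        group_map = read_group_map(group_map)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in group_map]
    if absent:
        raise GroupMapError(f"samples missing from group map: {absent[:5]}")

    chroms, poss, refs, alts, calls, missfracs = [], [], [], [], [], []
    log = {"multiallelic": 0, "non_snp": 0, "high_missing": 0, "retained": 0}
    for var in vcf:
        if len(var.ALT) != 1:
            log["multiallelic"] += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            log["non_snp"] += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :2].astype(np.int8)
        miss = float((gt < 0).mean())
        if miss > max_missing:
            log["high_missing"] += 1
            continue
        gt[gt < 0] = -1
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        calls.append(gt.reshape(-1))
        missfracs.append(miss)
        log["retained"] += 1
    logger.info("load_genotypes: %s", log)
    return GenotypeMatrix(
        chrom=np.asarray(chroms),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs),
        alt=np.asarray(alts),
        calls=(np.vstack(calls) if calls else np.empty((0, 2 * len(samples)), dtype=np.int8)),
        samples=samples,
        sample_groups={s: group_map[s] for s in samples},
        missing_frac=np.asarray(missfracs),
        filter_log=log,
    )


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str  # "." for intergenic
    category: str
    coding_subtype: str = "none"


def _load_gff_db(gff3: str | Path | gffutils.FeatureDB) -> gffutils.FeatureDB:
    if isinstance(gff3, gffutils.FeatureDB):
        return gff3
    return gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )


def _cds_layout(db: gffutils.FeatureDB, gene) -> tuple[list, str | None]:
    """Ordered CDS segments of the gene's first mRNA, or a warning reason."""
    mrnas = list(db.children(gene, featuretype="mRNA"))
    feats = list(db.children(mrnas[0] if mrnas else gene, featuretype="CDS"))
    if not feats:
        return [], "no_cds"
    feats.sort(key=lambda f: f.start, reverse=(gene.strand == "-"))
    phase = feats[0].frame
    offset = int(phase) if phase not in (None, ".", "") else 0
    total = sum(f.end - f.start + 1 for f in feats) - offset
    if total % 3 != 0:
        return feats, "cds_not_multiple_of_3"
    return feats, None


def _codon_effect(db, genome, gene, chrom: str, pos: int, ref: str, alt: str) -> str:
    """Translate ref vs alt codon at a CDS position; 'none' when not callable."""
    feats, warn = _cds_layout(db, gene)
    in_cds = any(f.start <= pos <= f.end for f in feats)
    if not in_cds:
        return "none"
    if warn == "cds_not_multiple_of_3":
        logger.warning("gene %s: CDS length not divisible by 3; codon effects skipped", gene.id)
        return "none"
    # index of the site within the spliced, strand-oriented CDS
    idx = 0
    phase0 = feats[0].frame
    offset = int(phase0) if phase0 not in (None, ".", "") else 0
    for f in feats:
        if f.start <= pos <= f.end:
            idx += (pos - f.start) if gene.strand != "-" else (f.end - pos)
            break
        idx += f.end - f.start + 1
    idx -= offset
    if idx < 0:
        return "none"
    cds_parts = []
    for f in feats:
        s = str(genome[chrom][f.start - 1 : f.end])
        cds_parts.append(s)
    cds = "".join(
        str(Seq(p).reverse_complement()) if gene.strand == "-" else p for p in cds_parts
    )
    cds = cds[offset:]
    codon_i = idx // 3
    codon = cds[3 * codon_i : 3 * codon_i + 3].upper()
    if len(codon) < 3:
        return "none"
    within = idx % 3
    ref_b, alt_b = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref_b = str(Seq(ref_b).reverse_complement())
        alt_b = str(Seq(alt_b).reverse_complement())
    if codon[within] != ref_b:
        logger.warning(
            "gene %s pos %d: reference base %s does not match CDS codon %s",
            gene.id, pos, ref_b, codon,
        )
    alt_codon = codon[:within] + alt_b + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    return "missense"


def classify_snp_effects(
    sites,
    gff3: str | Path | gffutils.FeatureDB,
    genome=None,
    flank: int = 5000,
) -> list[EffectRecord]:
    """Classify each SNP against a gene annotation.

    ``sites`` is a GenotypeMatrix or an iterable of (chrom, pos, ref, alt).
    ``genome`` (a pyfaidx.Fasta or any mapping of chrom -> sliceable
    sequence) is needed only for codon-level calls inside CDS; without it,
    exon SNPs get coding_subtype 'none'.

    One record per overlapping gene; one upstream/downstream record per gene
    whose strand-aware flank covers the site; a single intergenic record when
    nothing else applies.
    """
    if isinstance(sites, GenotypeMatrix):
        site_iter = list(zip(sites.chrom, sites.pos, sites.ref, sites.alt))
    else:
        site_iter = list(sites)

    db = _load_gff_db(gff3)
    gene_tree: dict[str, IntervalTree] = {}
    genes = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = g
        lo = max(0, g.start - 1 - flank)
        gene_tree.setdefault(g.seqid, IntervalTree()).addi(lo, g.end + flank, g.id)

    exon_tree: dict[str, IntervalTree] = {}
    for g in db.features_of_type("gene"):
        exons = list(db.children(g, featuretype="exon"))
        if not exons:
            exons = list(db.children(g, featuretype="CDS"))
        for e in exons:
            exon_tree.setdefault(g.id, IntervalTree()).addi(e.start - 1, e.end)

    records: list[EffectRecord] = []
    for chrom, pos, ref, alt in site_iter:
        chrom, pos = str(chrom), int(pos)
        hits = gene_tree.get(chrom, IntervalTree())[pos - 1]
        site_records = []
        for hit in sorted(hits, key=lambda h: h.data):
            g = genes[hit.data]
            if g.start <= pos <= g.end:
                in_exon = bool(exon_tree.get(g.id, IntervalTree())[pos - 1])
                if in_exon:
                    sub = (
                        _codon_effect(db, genome, g, chrom, pos, str(ref), str(alt))
                        if genome is not None
                        else "none"
                    )
                    site_records.append(EffectRecord(chrom, pos, str(ref), str(alt), g.id, "exon", sub))
                else:
                    site_records.append(EffectRecord(chrom, pos, str(ref), str(alt), g.id, "intron"))
            else:
                before = pos < g.start
                upstream = before if g.strand != "-" else not before
                cat = "upstream" if upstream else "downstream"
                site_records.append(EffectRecord(chrom, pos, str(ref), str(alt), g.id, cat))
        if not site_records:
            site_records.append(EffectRecord(chrom, pos, str(ref), str(alt), ".", "intergenic"))
        records.extend(site_records)
    return records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def percent_of(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total rounded half-up to ``decimals`` places."""
    if total == 0:
        raise ZeroDivisionError("total is 0")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def effect_percentages(counts: dict[str, int], decimals: int = 2) -> pd.DataFrame:
    """Per-category counts and percentages of total effect records."""
    total = sum(counts.values())
    rows = []
    for cat in CATEGORIES:
        if cat in counts:
            rows.append((cat, counts[cat], percent_of(counts[cat], total, decimals)))
    for cat in counts:
        if cat not in CATEGORIES:
            rows.append((cat, counts[cat], percent_of(counts[cat], total, decimals)))
    df = pd.DataFrame(rows, columns=["category", "count", "percent"])
    df.attrs["total_effects"] = total
    return df


def summarize_effects(records) -> pd.DataFrame:
    """Count effect records per category; percentages over records (not SNPs).

    Empty input yields an empty frame with total 0.
    """
    counts: dict[str, int] = {}
    for r in records:
        counts[r.category] = counts.get(r.category, 0) + 1
    if not counts:
        df = pd.DataFrame(columns=["category", "count", "percent"])
        df.attrs["total_effects"] = 0
        return df
    return effect_percentages(counts)
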