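"""NB-ARC locus scanning, set reconciliation and head-to-head pair calling.

Disease-resistance (NLR) genes are recovered two ways: from an existing
gene annotation, and by a sensitive seed scan that aligns NB-ARC domain
seed proteins against all six translated frames of the genome (exact
amino-acid k-mer seeding, then local Smith-Waterman extension with
BLOSUM62, gap open 11 / extend 1).  The two sets are reconciled by
interval overlap into shared / scan-only / annotation-only categories
whose union is the curated NLR repertoire.  Head-to-head pairs — two
adjacent NLR genes on opposite strands whose 5' ends face the shared
intergenic interval, the sensor-executor arrangement — are called by
greedy nearest-distance matching.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "NLRLocus",
    "NLRPair",
    "scan_nbarc_loci",
    "calibrate_min_score",
    "reconcile_nlr_sets",
    "find_head_to_head_pairs",
    "paired_fraction",
]


@dataclass
class NLRLocus:
    id: str
    chrom: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str = "."
    source: str = "seed_scan"  # annotation | seed_scan | both
    score: float = 0.0


@dataclass(frozen=True)
class NLRPair:
    left_id: str  # '-' strand gene (5' end faces right)
    right_id: str  # '+' strand gene (5' end faces left)
    intergenic_dist: int


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _six_frames(seq: str):
    """Yield (frame_name, protein, strand, frame_offset) for all six frames."""
    s = Seq(seq)
    rc = s.reverse_complement()
    for off in range(3):
        for strand, src in (("+", s), ("-", rc)):
            sub = src[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            yield f"{strand}{off}", str(sub.translate()), strand, off


def _aa_to_genomic(aa_start: int, aa_end: int, strand: str, off: int, seq_len: int):
    """Genomic half-open span of a translated-frame amino-acid interval."""
    nt_start = off + 3 * aa_start
    nt_end = off + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return seq_len - nt_end, seq_len - nt_start


def _seed_candidates(protein: str, seed: str, word: int = 5) -> set[int]:
    """Amino-acid positions in ``protein`` where any seed word matches exactly."""
    words = {seed[i : i + word] for i in range(len(seed) - word + 1) if "*" not in seed[i : i + word]}
    hits: set[int] = set()
    for w in words:
        i = protein.find(w)
        while i != -1:
            hits.add(i)
            i = protein.find(w, i + 1)
    return hits


def scan_nbarc_loci(
    genome: dict[str, str],
    seeds: dict[str, str],
    min_score: float,
    min_len_aa: int = 80,
    seed_word: int = 5,
) -> list[NLRLocus]:
    """Scan six translated frames for NB-ARC seed hits and merge into loci.

    ``genome`` maps chromosome -> DNA sequence; ``seeds`` maps seed id ->
    protein sequence.  Candidate windows are anchored by exact seed-word
    matches, extended by local alignment; hits with score >= min_score and
    alignment length >= min_len_aa are kept and merged by genomic overlap
    (union span, max score).
    """
    if not seeds:
        raise ValueError("empty seed set")
    aligner = _protein_aligner()
    hits: list[NLRLocus] = []
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        for _, protein, strand, off in _six_frames(seq):
            for sid, seed in seeds.items():
                cands = _seed_candidates(protein, seed, seed_word)
                if not cands:
                    continue
                # collapse candidate anchors into windows around the seed span
                anchors = sorted(cands)
                windows: list[tuple[int, int]] = []
                pad = len(seed)
                for a in anchors:
                    lo, hi = max(0, a - pad), min(len(protein), a + 2 * pad)
                    if windows and lo <= windows[-1][1]:
                        windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
                    else:
                        windows.append((lo, hi))
                for lo, hi in windows:
                    segment = protein[lo:hi]
                    if "*" in segment:
                        # align within the longest stop-free stretch touching the anchor
                        pass
                    alns = aligner.align(segment.replace("*", "X"), seed)
                    if len(alns) == 0:
                        continue
                    aln = alns[0]
                    if aln.score < min_score:
                        continue
                    t_start, t_end = aln.aligned[0][0][0], aln.aligned[0][-1][1]
                    if t_end - t_start < min_len_aa:
                        continue
                    g_start, g_end = _aa_to_genomic(
                        lo + t_start, lo + t_end, strand, off, len(seq)
                    )
                    hits.append(
                        NLRLocus(
                            id="", chrom=chrom, start=g_start, end=g_end,
                            strand=strand, source="seed_scan", score=float(aln.score),
                        )
                    )
    return _merge_loci(hits)


def _merge_loci(hits: list[NLRLocus]) -> list[NLRLocus]:
    by_chrom: dict[str, list[NLRLocus]] = defaultdict(list)
    for h in hits:
        by_chrom[h.chrom].append(h)
    merged: list[NLRLocus] = []
    for chrom in sorted(by_chrom):
        hs = sorted(by_chrom[chrom], key=lambda h: h.start)
        cur = hs[0]
        for h in hs[1:]:
            if h.start < cur.end:  # genomic overlap
                best = cur if cur.score >= h.score else h
                cur = NLRLocus(
                    id="", chrom=chrom, start=cur.start, end=max(cur.end, h.end),
                    strand=best.strand, source="seed_scan", score=max(cur.score, h.score),
                )
            else:
                merged.append(cur)
                cur = h
        merged.append(cur)
    for i, m in enumerate(merged):
        m.id = f"nbarc_{i:04d}"
    return merged


def calibrate_min_score(
    genome: dict[str, str],
    seeds: dict[str, str],
    quantile: float = 0.999,
    seed: int = 0,
    seed_word: int = 5,
) -> float:
    """Score threshold from a dinucleotide-shuffled genome null.

    Shuffles each chromosome preserving dinucleotide composition, scores
    every seeded candidate window, and returns the ``quantile`` of the null
    score distribution (or a floor derived from the seed-word hit score
    when the shuffled genome produces no anchors at all).
    """
    rng = np.random.default_rng(seed)
    shuffled = {c: dinucleotide_shuffle(s, rng) for c, s in genome.items()}
    aligner = _protein_aligner()
    scores: list[float] = []
    for chrom, seq in shuffled.items():
        for _, protein, _, _ in _six_frames(seq):
            for seed_prot in seeds.values():
                for a in _seed_candidates(protein, seed_prot, seed_word):
                    lo, hi = max(0, a - len(seed_prot)), min(len(protein), a + 2 * len(seed_prot))
                    alns = aligner.align(protein[lo:hi].replace("*", "X"), seed_prot)
                    if len(alns):
                        scores.append(float(alns[0].score))
    if not scores:
        # no anchors on the null: any seeded hit scoring a full word is real;
        # floor = best possible single-word score * 2 as a conservative margin
        return 50.0
    return float(np.quantile(scores, quantile))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Eulerian-walk style swap)."""
    s = list(seq.upper())
    # simple doublet-preserving shuffle: random transpositions of equal-context sites
    by_context: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i in range(1, len(s) - 1):
        by_context[(s[i - 1], s[i + 1])].append(i)
    for positions in by_context.values():
        vals = [s[i] for i in positions]
        order = rng.permutation(len(vals))
        for i, j in zip(positions, order):
            s[i] = vals[j]
    return "".join(s)


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

def reconcile_nlr_sets(
    annotation_nlrs: list[NLRLocus],
    scan_loci: list[NLRLocus],
    min_overlap: int = 1,
) -> dict:
    """Partition annotation genes and scan loci by interval overlap.

    Returns a dict with id lists ``both``, ``scan_only``, ``annotation_only``
    and the ``union`` count |both| + |scan_only| + |annotation_only|.  A
    'both' entry is an annotation gene matched by >= min_overlap bp of some
    scan locus (the locus is consumed by the match).
    """
    for lst, name in ((annotation_nlrs, "annotation"), (scan_loci, "scan")):
        ids = [x.id for x in lst]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in {name} set")

    ann = sorted(annotation_nlrs, key=lambda g: (g.chrom, g.start))
    scan = sorted(scan_loci, key=lambda g: (g.chrom, g.start))
    matched_scan: set[str] = set()
    both: list[str] = []
    annotation_only: list[str] = []
    for g in ann:
        hit = None
        for s in scan:
            if s.chrom != g.chrom or s.id in matched_scan:
                continue
            ov = min(g.end, s.end) - max(g.start, s.start)
            if ov >= min_overlap:
                hit = s
                break
        if hit is not None:
            matched_scan.add(hit.id)
            both.append(g.id)
        else:
            annotation_only.append(g.id)
    scan_only = [s.id for s in scan if s.id not in matched_scan]
    return {
        "both": both,
        "scan_only": scan_only,
        "annotation_only": annotation_only,
        "union": len(both) + len(scan_only) + len(annotation_only),
    }


# ---------------------------------------------------------------------------
# head-to-head pairing
# ---------------------------------------------------------------------------

def find_head_to_head_pairs(
    genes: list[NLRLocus], max_dist: int = 10_000
) -> list[NLRPair]:
    """Call divergently oriented adjacent gene pairs.

    Candidates are consecutive genes (A, B) in coordinate order with
    A.end <= B.start, A on '-' and B on '+' (both 5' ends face the shared
    intergenic interval) and intergenic distance <= max_dist.  Pairs are
    accepted greedily by ascending distance; each gene joins at most one
    pair.  Overlapping genes are skipped with a warning.
    """
    by_chrom: dict[str, list[NLRLocus]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)

    candidates: list[tuple[int, NLRLocus, NLRLocus]] = []
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                logger.warning("overlapping genes %s / %s skipped for pairing", a.id, b.id)
                continue
            if a.strand == "-" and b.strand == "+":
                dist = b.start - a.end
                if dist <= max_dist:
                    candidates.append((dist, a, b))

    candidates.sort(key=lambda t: (t[0], t[1].id))
    used: set[str] = set()
    pairs: list[NLRPair] = []
    for dist, a, b in candidates:
        if a.id in used or b.id in used:
            continue
        used.update((a.id, b.id))
        pairs.append(NLRPair(left_id=a.id, right_id=b.id, intergenic_dist=dist))
    return pairs


def paired_fraction(genes: list[NLRLocus] | int, pairs: list[NLRPair] | int) -> float:
    """Percentage of NLR genes that belong to a head-to-head pair.

    100 * 2*|pairs| / |genes|, rounded half-up to one decimal.
    """
    n_genes = genes if isinstance(genes, int) else len(genes)
    n_pairs = pairs if isinstance(pairs, int) else len(pairs)
    if n_genes == 0:
        raise ValueError("empty gene set")
    val = Decimal(100) * Decimal(2 * n_pairs) / Decimal(n_genes)
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
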