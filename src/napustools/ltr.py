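"""LTR retrotransposon insertion dating and centromeric enrichment.

A retrotransposon's two terminal repeats are identical at insertion and
diverge neutrally afterwards, so their pairwise distance K dates the
insertion as T = K / (2 r), with r the per-site per-year substitution
rate (default 1.4e-8).  Divergence is measured on a global alignment of
the 5' and 3' LTRs (match +1, mismatch -2, gap open -4, gap extend -1);
the p-distance uses gap-free, N-free columns and is optionally corrected
with Jukes-Cantor, K = -(3/4) ln(1 - 4p/3).

Dated elements are profiled into age histograms and three age groups
(<0.2 My, 0.2-1 My, >1 My) and tested for centromeric enrichment
(element midpoint inside a centromere interval; Fisher exact test of
young vs older elements).  A simplified flank test checks whether an
element is present or absent at the syntenic site of a second genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

AGE_GROUPS = ("<0.2My", "0.2-1My", ">1My")
DEFAULT_RATE = 1.4e-8  # substitutions / site / year

__all__ = [
    "LTRElement",
    "ltr_divergence",
    "insertion_age",
    "age_group",
    "date_elements",
    "age_profile",
    "centromere_enrichment",
    "flank_presence_test",
    "DEFAULT_RATE",
]


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor saturation bound (0.75)."""


class AlignmentError(ValueError):
    pass


@dataclass
class LTRElement:
    id: str
    chrom: str | None = None
    start: int | None = None  # 0-based half-open element span
    end: int | None = None
    seq5: str = ""
    seq3: str = ""
    aligned_sites: int = 0
    mismatches: int = 0
    p_distance: float = math.nan
    K: float = math.nan
    T: float = math.nan
    age_group: str | None = None


def _ltr_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-2,
        open_gap_score=-4, extend_gap_score=-1,
    )


def ltr_divergence(
    seq5: str, seq3: str, correction: str = "JC69"
) -> tuple[float, float, int, int]:
    """Pairwise divergence of the two terminal repeats.

    Returns (p_distance, K, aligned_sites, mismatches).  Columns containing
    a gap or an N are excluded from the aligned-site count.
    """
    if not seq5 or not seq3:
        raise AlignmentError("empty LTR sequence")
    seq5, seq3 = seq5.upper(), seq3.upper()
    if seq5 == seq3:
        aligned = sum(b not in "N" for b in seq5)
        if aligned == 0:
            raise AlignmentError("no gap-free, N-free aligned columns")
        return 0.0, 0.0, aligned, 0
    aln = _ltr_aligner().align(seq5, seq3)[0]
    a, b = str(aln[0]), str(aln[1])
    aligned = 0
    mism = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        aligned += 1
        if x != y:
            mism += 1
    if aligned == 0:
        raise AlignmentError("no gap-free, N-free aligned columns")
    p = mism / aligned
    if correction.upper() == "JC69":
        if p >= 0.75:
            raise SaturationError(f"p = {p:.3f} >= 0.75: JC69 distance undefined")
        K = -0.75 * math.log(1 - 4 * p / 3)
    elif correction.lower() == "raw":
        K = p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return p, K, aligned, mism


def age_group(t_years: float) -> str:
    """Partition of ages: [0, 0.2 My), [0.2 My, 1 My], (1 My, inf)."""
    if t_years < 2e5:
        return AGE_GROUPS[0]
    if t_years <= 1e6:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def insertion_age(K: float, rate: float = DEFAULT_RATE) -> tuple[float, str]:
    """T = K / (2 r) in years, plus the age group."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    T = K / (2 * rate)
    return T, age_group(T)


def date_elements(
    elements: list[LTRElement],
    rate: float = DEFAULT_RATE,
    correction: str = "JC69",
) -> list[LTRElement]:
    """Date every element in place; saturated elements stay NaN with a log entry."""
    for el in elements:
        try:
            el.p_distance, el.K, el.aligned_sites, el.mismatches = ltr_divergence(
                el.seq5, el.seq3, correction
            )
        except (SaturationError, AlignmentError) as exc:
            logger.warning("element %s not datable: %s", el.id, exc)
            continue
        el.T, el.age_group = insertion_age(el.K, rate)
    return elements


def load_elements(table_path: str | Path, fasta) -> list[LTRElement]:
    """Build elements from a coordinate table plus an indexed FASTA.

    The table needs columns id, ltr5_start/end, ltr3_start/end (0-based
    half-open within the named FASTA record; the record name defaults to
    the id itself, or a 'seqid' column).
    """
    df = pd.read_csv(table_path, sep="\t")
    out = []
    for row in df.itertuples():
        seqid = getattr(row, "seqid", row.id)
        seq = str(fasta[seqid][:])
        out.append(
            LTRElement(
                id=row.id,
                seq5=seq[row.ltr5_start : row.ltr5_end],
                seq3=seq[row.ltr3_start : row.ltr3_end],
            )
        )
    return out


# ---------------------------------------------------------------------------
# profiles and enrichment
# ---------------------------------------------------------------------------

def age_profile(
    ages_years,
    bin_width_young: float = 10_000,
    young_range: tuple[float, float] = (0.0, 5e5),
    bin_width_old: float = 100_000,
    old_range: tuple[float, float] = (0.0, 5e6),
) -> dict[str, pd.DataFrame]:
    """Two age histograms: fine-grained recent bins and coarse long-range bins."""
    ages = np.asarray([a for a in ages_years if np.isfinite(a)], dtype=float)
    out = {}
    for name, width, (lo, hi) in (
        ("young", bin_width_young, young_range),
        ("old", bin_width_old, old_range),
    ):
        edges = np.arange(lo, hi + width / 2, width)
        counts, _ = np.histogram(ages, bins=edges)
        out[name] = pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
        )
    return out


def _read_bed_trees(bed_path: str | Path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            trees.setdefault(f[0], IntervalTree()).addi(int(f[1]), int(f[2]))
    return trees


def centromere_enrichment(
    elements: pd.DataFrame, centromere_bed: str | Path
) -> tuple[pd.DataFrame, float]:
    """Centromeric fraction per age group + Fisher exact p (young vs older).

    ``elements`` needs columns chrom, start, end, age_group.  An element is
    centromeric when its midpoint lies inside any centromere interval of
    its chromosome; chromosomes absent from the BED count as outside.
    """
    trees = _read_bed_trees(centromere_bed)
    warned: set[str] = set()
    inside = []
    for row in elements.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            if row.chrom not in warned:
                logger.warning("chromosome %s absent from centromere BED", row.chrom)
                warned.add(row.chrom)
            inside.append(False)
            continue
        mid = (row.start + row.end) // 2
        inside.append(bool(tree[mid]))
    df = elements.assign(in_centromere=inside)

    rows = []
    for grp in AGE_GROUPS:
        sub = df[df["age_group"] == grp]
        frac = float(sub["in_centromere"].mean()) if len(sub) else 0.0
        rows.append((grp, len(sub), int(sub["in_centromere"].sum()), frac))
    table = pd.DataFrame(rows, columns=["age_group", "n", "n_centromeric", "fraction"])

    young = df["age_group"] == AGE_GROUPS[0]
    cont = [
        [int(df[young]["in_centromere"].sum()), int((~df[young]["in_centromere"]).sum())],
        [int(df[~young]["in_centromere"].sum()), int((~df[~young]["in_centromere"]).sum())],
    ]
    if min(sum(r) for r in cont) == 0:
        p = math.nan
    else:
        _, p = stats.fisher_exact(cont)
    return table, float(p)


# ---------------------------------------------------------------------------
# flank presence test
# ---------------------------------------------------------------------------

def _map_flank(
    flank: str, genome_seq: str, min_identity: float, seed_len: int = 31, max_hits: int = 3
):
    """Exact-seed + extension placement of one flank; None if unresolved."""
    seed = flank[: seed_len] if len(flank) >= seed_len else flank
    hits = []
    i = genome_seq.find(seed)
    while i != -1:
        hits.append(i)
        if len(hits) > max_hits:
            return None  # repetitive flank
        i = genome_seq.find(seed, i + 1)
    placements = []
    for h in hits:
        window = genome_seq[h : h + int(1.2 * len(flank))]
        res = edlib.align(flank, window, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        ident = 1 - res["editDistance"] / len(flank)
        if ident >= min_identity:
            loc = res["locations"][0]
            placements.append((h + loc[0], h + loc[1] + 1))
    if len(placements) != 1:
        return None
    return placements[0]


def flank_presence_test(
    element_seq: str,
    left_flank: str,
    right_flank: str,
    other_genome: str,
    flank_len: int = 1000,
    min_identity: float = 0.9,
) -> str:
    """Classify an element's status at the syntenic site of another genome.

    Locates both flanks in ``other_genome`` by exact seeding + extension:
    flanks mapping adjacently (gap < 0.1 x element length) mean the site is
    empty -> 'absent_specific'; flanks separated by >= 0.9 x element length
    with element-like sequence between -> 'present'; anything else,
    including repetitive or unmappable flanks -> 'unresolved'.
    """
    if len(left_flank) < flank_len or len(right_flank) < flank_len:
        raise ValueError(f"flanks must be >= {flank_len} bp")
    left = left_flank[-flank_len:]
    right = right_flank[:flank_len]
    lmap = _map_flank(left, other_genome, min_identity)
    rmap = _map_flank(right, other_genome, min_identity)
    if lmap is None or rmap is None:
        return "unresolved"
    gap = rmap[0] - lmap[1]
    if gap < 0:
        return "unresolved"
    if gap < 0.1 * len(element_seq):
        return "absent_specific"
    if gap >= 0.9 * len(element_seq):
        middle = other_genome[lmap[1] : rmap[0]]
        res = edlib.align(element_seq, middle, mode="NW", task="distance")
        ident = 1 - res["editDistance"] / max(len(element_seq), len(middle))
        if ident >= min_identity:
            return "present"
    return "unresolved"
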