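"""Windowed diversity / differentiation scan and sweep-region calling.

The scan computes, in sliding windows (default 100 kb windows, 10 kb
steps, anchored at position 0 of each chromosome):

* nucleotide diversity pi per group — per site, the unbiased estimator
  c_ref*c_alt / C(n,2) over non-missing haploid calls, summed over sites
  and divided by the nominal window length (monomorphic/unobserved bases
  contribute zero);
* the Weir & Cockerham (1984) two-population FST from diploid variance
  components a (among populations), b (among individuals within
  populations) and c (within individuals), windowed as the ratio of sums
  sum(a) / sum(a+b+c) — the "weighted" estimator; negative values are kept;
* the pi ratio between the two groups.

Sweep windows are the joint extremal tails: FST in the empirical top-q
tail and the pi ratio in either the lower tail (diversity lost in the
numerator group) or the upper tail (lost in the denominator group).
Overlapping or abutting significant windows of the same selected group
merge into sweep regions, which are then annotated with overlapping
genes, NLR ids and QTL intervals (half-open intervals, >=1 bp rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .variants import GenotypeMatrix, _load_gff_db

logger = logging.getLogger(__name__)

__all__ = [
    "WindowStat",
    "SweepRegion",
    "window_pi",
    "window_fst",
    "scan_windows",
    "empirical_threshold",
    "call_sweeps",
    "overlap_annotations",
    "site_pi",
    "site_fst_components",
]


class DegenerateDistributionError(ValueError):
    pass


@dataclass
class WindowStat:
    chrom: str
    start: int  # 0-based half-open
    end: int
    pi_a: float
    pi_b: float
    pi_ratio: float
    fst: float
    n_snps: int
    partial: bool = False


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    selected_group: str
    n_windows: int
    mean_fst: float
    mean_pi_ratio: float
    genes: list[str] = field(default_factory=list)
    nlr_ids: list[str] = field(default_factory=list)
    qtl_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_pi(calls: np.ndarray) -> np.ndarray:
    """Per-site pi over haploid calls (sites x haplotypes; -1 = missing).

    pi_j = c_ref * c_alt / C(n_j, 2); sites with n_j < 2 return 0 and are
    effectively skipped (they cannot contribute pairwise differences).
    """
    valid = calls >= 0
    n = valid.sum(axis=1)
    c_alt = np.where(valid, calls, 0).sum(axis=1)
    c_ref = n - c_alt
    pairs = n * (n - 1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(pairs > 0, c_ref * c_alt / pairs, 0.0)
    return pi


def site_fst_components(gt_a: np.ndarray, gt_b: np.ndarray) -> tuple[np.ndarray, ...]:
    """Weir & Cockerham (1984) variance components per site, two populations.

    ``gt_a``/``gt_b``: diploid genotype arrays, shape (sites, samples, 2),
    allele index 0/1 with -1 missing.  A diploid is used only when both of
    its alleles are called.  Returns (a, b, c) arrays.
    """
    comps = []
    for gt in (gt_a, gt_b):
        called = (gt >= 0).all(axis=2)
        n_i = called.sum(axis=1).astype(float)  # diploids with full calls
        alt = np.where(called[:, :, None], gt, 0).sum(axis=(1, 2)).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * n_i), np.nan)
        het = (called & (gt[:, :, 0] != gt[:, :, 1])).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_i = np.where(n_i > 0, het / n_i, np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    # sites unusable for the estimator: <2 diploids in either group
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(a + b + c)
    for arr in (a, b, c):
        arr[bad] = 0.0
    return a, b, c


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def _window_grid(chrom_len: int, window: int, step: int) -> list[tuple[int, int, bool]]:
    """0-anchored sliding windows; trailing partial windows flagged."""
    out = []
    start = 0
    while start < chrom_len:
        end = start + window
        out.append((start, min(end, chrom_len), end > chrom_len))
        start += step
    return out


def _group_gt(matrix: GenotypeMatrix, group: str) -> np.ndarray:
    cols = matrix.group_columns(group)
    return matrix.calls[:, cols].reshape(matrix.n_sites, -1, 2)


def window_pi(
    matrix: GenotypeMatrix,
    group: str,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed nucleotide diversity per bp for one group."""
    df = scan_windows(matrix, group, None, window, step, chrom_lengths)
    return df[["chrom", "start", "end", "pi_a", "n_snps", "partial"]].rename(
        columns={"pi_a": "pi"}
    )


def window_fst(
    matrix: GenotypeMatrix,
    group_a: str,
    group_b: str,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham FST (ratio of sums) for two groups."""
    df = scan_windows(matrix, group_a, group_b, window, step, chrom_lengths)
    return df[["chrom", "start", "end", "fst", "n_snps", "partial"]]


def scan_windows(
    matrix: GenotypeMatrix,
    group_a: str,
    group_b: str | None,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Joint windowed pi (both groups), pi ratio and FST.

    With ``group_b=None`` only pi of ``group_a`` is computed.  Window pi
    divides by the nominal window length; FST in windows with
    sum(a+b+c) = 0 is NaN (flagged, excluded from quantiles downstream).
    """
    calls_a = _group_gt(matrix, group_a).reshape(matrix.n_sites, -1)
    pi_a = site_pi(calls_a)
    if group_b is not None:
        gt_a = _group_gt(matrix, group_a)
        gt_b = _group_gt(matrix, group_b)
        pi_b = site_pi(gt_b.reshape(matrix.n_sites, -1))
        a, b, c = site_fst_components(gt_a, gt_b)
    else:
        pi_b = np.zeros(matrix.n_sites)
        a = b = c = np.zeros(matrix.n_sites)

    rows = []
    for chrom in pd.unique(matrix.chrom):
        mask = matrix.chrom == chrom
        pos0 = matrix.pos[mask] - 1  # to 0-based
        order = np.argsort(pos0)
        pos0 = pos0[order]
        idx = np.where(mask)[0][order]
        clen = (chrom_lengths or {}).get(
            str(chrom), int(pos0[-1]) + 1 if len(pos0) else window
        )
        for start, end, partial in _window_grid(clen, window, step):
            lo, hi = np.searchsorted(pos0, [start, end])
            sel = idx[lo:hi]
            n_snps = len(sel)
            w_pi_a = float(pi_a[sel].sum() / window)
            w_pi_b = float(pi_b[sel].sum() / window)
            denom = float((a[sel] + b[sel] + c[sel]).sum())
            fst = float(a[sel].sum() / denom) if denom != 0 else math.nan
            if group_b is not None:
                if w_pi_b > 0:
                    ratio = w_pi_a / w_pi_b
                elif w_pi_a > 0:
                    ratio = math.inf
                else:
                    ratio = math.nan  # both groups zero: excluded
            else:
                ratio = math.nan
            rows.append((str(chrom), start, end, w_pi_a, w_pi_b, ratio, fst, n_snps, partial))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "pi_a", "pi_b", "pi_ratio", "fst", "n_snps", "partial"],
    )


# ---------------------------------------------------------------------------
# empirical quantile thresholds and sweep calling
# ---------------------------------------------------------------------------

def empirical_threshold(
    values, tail: str = "upper", q: float = 0.05
) -> tuple[float, np.ndarray]:
    """Empirical top/bottom-q threshold with ties kept together.

    Upper tail: the smallest value v such that #{x >= v} <= ceil(q*N);
    returns (v, indices of retained values).  Lower tail symmetric.
    Requires >= 20 finite values; a constant vector is degenerate.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    v = values[finite]
    if len(v) < 20:
        raise ValueError(f"need >= 20 finite values, got {len(v)}")
    if np.all(v == v[0]):
        raise DegenerateDistributionError("all values identical")
    k = math.ceil(q * len(v))
    uniq = np.unique(v)  # ascending
    if tail == "upper":
        # count of x >= u for each unique u
        counts = len(v) - np.searchsorted(v[np.argsort(v)], uniq, side="left")
        ok = uniq[counts <= k]
        if len(ok) == 0:
            thr = math.inf
        else:
            thr = float(ok.min())
        retained = np.where(finite & (values >= thr))[0]
    elif tail == "lower":
        counts = np.searchsorted(np.sort(v), uniq, side="right")
        ok = uniq[counts <= k]
        thr = float(ok.max()) if len(ok) else -math.inf
        retained = np.where(finite & (values <= thr))[0]
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return thr, retained


def call_sweeps(
    stats: pd.DataFrame,
    group_a: str,
    group_b: str,
    q_fst: float = 0.05,
    q_pi: float = 0.05,
) -> list[SweepRegion]:
    """Joint extremal-tail sweep calling and region merging.

    A window is significant when its FST reaches the upper ``q_fst`` tail
    and its pi ratio (group_a / group_b) reaches either pi-ratio tail:
    lower tail -> diversity lost in group_a (selected = group_a); upper
    tail (including +inf sentinels) -> selected = group_b.  Significant
    windows of one selected group that overlap or abut merge into regions.
    """
    df = stats.copy()
    usable = np.isfinite(df["fst"].to_numpy())
    ratio = df["pi_ratio"].to_numpy(dtype=float)
    has_ratio = ~np.isnan(ratio)
    excluded = int((~usable | ~has_ratio).sum())
    if excluded:
        logger.info("call_sweeps: %d windows excluded (undefined FST or pi ratio)", excluded)

    fst_vals = np.where(usable, df["fst"].to_numpy(), np.nan)
    _, fst_idx = empirical_threshold(fst_vals, "upper", q_fst)
    fst_sig = np.zeros(len(df), dtype=bool)
    fst_sig[fst_idx] = True

    # +inf ratios belong to the upper tail by construction; thresholds are
    # computed on the finite part
    finite_ratio = np.where(np.isfinite(ratio), ratio, np.nan)
    _, lo_idx = empirical_threshold(finite_ratio, "lower", q_pi)
    _, hi_idx = empirical_threshold(finite_ratio, "upper", q_pi)
    lo_sig = np.zeros(len(df), dtype=bool)
    lo_sig[lo_idx] = True
    hi_sig = np.zeros(len(df), dtype=bool)
    hi_sig[hi_idx] = True
    hi_sig |= np.isposinf(ratio)

    sig_a = fst_sig & lo_sig  # numerator group lost diversity
    sig_b = fst_sig & hi_sig & ~sig_a

    regions: list[SweepRegion] = []
    for sel_group, sig in ((group_a, sig_a), (group_b, sig_b)):
        sub = df[sig].sort_values(["chrom", "start"])
        cur = None
        for row in sub.itertuples():
            if (
                cur is not None
                and row.chrom == cur["chrom"]
                and row.start <= cur["end"]  # overlap or abut
            ):
                cur["end"] = max(cur["end"], row.end)
                cur["fst"].append(row.fst)
                cur["ratio"].append(row.pi_ratio)
                cur["n"] += 1
            else:
                if cur is not None:
                    regions.append(_finish_region(cur, sel_group))
                cur = {
                    "chrom": row.chrom,
                    "start": row.start,
                    "end": row.end,
                    "fst": [row.fst],
                    "ratio": [row.pi_ratio],
                    "n": 1,
                }
        if cur is not None:
            regions.append(_finish_region(cur, sel_group))
    regions.sort(key=lambda r: (r.chrom, r.start, r.selected_group))
    return regions


def _finish_region(cur: dict, group: str) -> SweepRegion:
    finite = [x for x in cur["ratio"] if math.isfinite(x)]
    return SweepRegion(
        chrom=cur["chrom"],
        start=int(cur["start"]),
        end=int(cur["end"]),
        selected_group=group,
        n_windows=cur["n"],
        mean_fst=float(np.mean(cur["fst"])),
        mean_pi_ratio=float(np.mean(finite)) if finite else math.inf,
    )


# ---------------------------------------------------------------------------
# annotation overlap
# ---------------------------------------------------------------------------

def _bed_tree(bed_path: str | Path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            trees.setdefault(f[0], IntervalTree()).addi(int(f[1]), int(f[2]), name)
    return trees


def overlap_annotations(
    regions: list[SweepRegion],
    gff3: str | Path | gffutils.FeatureDB | None = None,
    nlr_ids: set[str] | None = None,
    qtl_bed: str | Path | None = None,
) -> list[SweepRegion]:
    """Attach overlapping gene / NLR / QTL ids to each region (>=1 bp rule).

    Gene coordinates (1-based inclusive GFF3) are converted to half-open
    before intersection.  A chromosome present in the regions but in none
    of the annotation sources raises a reconciliation error.
    """
    gene_trees: dict[str, IntervalTree] = {}
    if gff3 is not None:
        db = _load_gff_db(gff3)
        for g in db.features_of_type("gene"):
            gene_trees.setdefault(g.seqid, IntervalTree()).addi(g.start - 1, g.end, g.id)
    qtl_trees = _bed_tree(qtl_bed) if qtl_bed is not None else {}

    known_chroms = set(gene_trees) | set(qtl_trees)
    if known_chroms:
        offenders = sorted({r.chrom for r in regions} - known_chroms)
        if offenders:
            raise ValueError(f"chromosomes absent from annotation sources: {offenders}")

    nlr_ids = set(nlr_ids or ())
    for r in regions:
        hits = sorted(h.data for h in gene_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end))
        r.genes = hits
        r.nlr_ids = [g for g in hits if g in nlr_ids]
        r.qtl_ids = sorted(
            h.data for h in qtl_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end)
        )
    return regions


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.chrom, r.start, r.end, r.selected_group, r.n_windows,
                r.mean_fst, r.mean_pi_ratio,
                ",".join(r.genes) or ".", ",".join(r.nlr_ids) or ".", ",".join(r.qtl_ids) or ".",
            )
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "selected_group", "n_windows",
            "mean_fst", "mean_pi_ratio", "genes", "nlr_ids", "qtl_ids",
        ],
    )
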