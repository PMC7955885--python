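"""Synthetic input generators for every pipeline stage.

Each generator is a pure function of its parameter object (including the
RNG seed): the same parameters always produce byte-identical output files.
They emit the standard text formats the analysis stages consume (VCFv4.2,
FASTA, GFF3, BED, TSV truth tables) so every downstream operation can be
exercised against planted truth without external data.

The population generator plants selective sweeps by deforming expected
allele frequencies: ancestral frequencies are drawn from a Beta
distribution shared across groups, each group's frequency is a binomial
resample of the ancestral one (creating mild background differentiation),
and inside a sweep window the selected group's minor-allele frequency is
collapsed toward fixation while the other groups are displaced toward the
opposite allele. Diploid genotypes are two independent haploid draws
(Hardy-Weinberg), which is exactly the sampling model the windowed
pi / Weir-Cockerham FST estimators assume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DNA = np.array(list("ACGT"))

__all__ = [
    "PopSimParams",
    "LTRSimParams",
    "SatelliteSimParams",
    "AnnotSimParams",
    "simulate_populations",
    "simulate_ltr_elements",
    "simulate_tandem_array_genome",
    "simulate_gene_annotation",
]


class SimulationParameterError(ValueError):
    """A simulation parameter violates its documented invariant."""


class PlacementError(RuntimeError):
    """Requested features cannot be placed without overlap on the chromosome."""


# ---------------------------------------------------------------------------
# parameter objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopSimParams:
    """Parameters of the two/three-group SNP panel with planted sweeps.

    ``sweep_windows`` maps window index -> selected group index.
    ``sweep_diversity_factor`` f reduces the selected group's minor-allele
    frequency to (1 - f) of its value; ``sweep_divergence_shift`` s moves
    every other group's frequency a fraction s of the way toward the allele
    the selected group is collapsing away from.
    """

    n_groups: int = 2
    samples_per_group: int = 20
    n_windows: int = 50
    window_len: int = 20_000
    snp_density: float = 0.005
    beta_alpha: float = 0.8
    beta_beta: float = 0.8
    sweep_windows: tuple[tuple[int, int], ...] = ()
    sweep_diversity_factor: float = 0.9
    sweep_divergence_shift: float = 0.6
    resample_n: int = 200
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sweep_diversity_factor < 1):
            raise SimulationParameterError("sweep_diversity_factor must be in [0, 1)")
        if not (0 <= self.sweep_divergence_shift <= 1):
            raise SimulationParameterError("sweep_divergence_shift must be in [0, 1]")
        if self.n_groups < 2:
            raise SimulationParameterError("need at least two groups")
        for w, g in self.sweep_windows:
            if not (0 <= w < self.n_windows):
                raise SimulationParameterError(f"sweep window index {w} out of range")
            if not (0 <= g < self.n_groups):
                raise SimulationParameterError(f"sweep group index {g} out of range")

    @property
    def chrom_len(self) -> int:
        return self.n_windows * self.window_len

    @property
    def group_names(self) -> list[str]:
        return [f"G{i}" for i in range(self.n_groups)]


@dataclass(frozen=True)
class LTRSimParams:
    """Parameters of the intact-LTR cohort with known insertion ages.

    Each element is 5'LTR + internal + 3'LTR; the two terminal repeats start
    identical and each accumulates substitutions independently with per-site
    probability rate*age, so the expected pairwise divergence is ~2*rate*age.
    Elements are placed on one virtual chromosome; the probability of landing
    inside the centromeric interval depends on the element's age group,
    emulating the centromeric clustering of recent insertions.
    """

    n_elements: int = 300
    ltr_len: int = 1000
    internal_len: int = 3000
    ages: tuple[float, ...] = (1e4, 1e5, 1e6)
    rate: float = 1.4e-8
    centromere_interval: tuple[int, int] = (2_000_000, 4_000_000)
    centromere_placement_prob_by_age_group: tuple[float, float, float] = (0.45, 0.29, 0.26)
    chrom_len: int = 0  # 0 -> derived as 3x centromere end
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.ages):
            raise SimulationParameterError("ages must be >= 0")
        if self.rate <= 0:
            raise SimulationParameterError("rate must be > 0")
        if any(not (0 <= p <= 1) for p in self.centromere_placement_prob_by_age_group):
            raise SimulationParameterError("placement probabilities must be in [0, 1]")
        if self.chrom_len == 0:
            object.__setattr__(self, "chrom_len", 3 * self.centromere_interval[1])

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len


@dataclass(frozen=True)
class SatelliteSimParams:
    """Parameters of a chromosome carrying one tandem satellite array."""

    monomer_len: int = 176
    n_copies: int = 5000
    substitution_rate_per_site: float = 0.02
    indel_rate: float = 0.0
    flank_len: int = 50_000
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.monomer_len < 2:
            raise SimulationParameterError("monomer_len must be >= 2")
        for r in (self.substitution_rate_per_site, self.indel_rate):
            if not (0 <= r < 1):
                raise SimulationParameterError("rates must be in [0, 1)")


@dataclass(frozen=True)
class AnnotSimParams:
    """Parameters of a gene annotation containing NLR clusters and pairs."""

    n_genes: int = 60
    n_nlr: int = 20
    n_pairs: int = 3
    pair_intergenic_dist: int = 2000
    gene_len: int = 3000
    chrom_len: int = 1_000_000
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 * self.n_pairs <= self.n_nlr <= self.n_genes):
            raise SimulationParameterError("need 2*n_pairs <= n_nlr <= n_genes")


# ---------------------------------------------------------------------------
# small writers (text formats, fixed layout for byte determinism)
# ---------------------------------------------------------------------------

def write_fasta(path: Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _mutate_subs(rng: np.random.Generator, seq: np.ndarray, p: float) -> np.ndarray:
    """Substitute each site with probability p, always to a different base."""
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    # shift by 1..3 mod 4 guarantees a change
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(DNA[seq])


# ---------------------------------------------------------------------------
# population / VCF generator
# ---------------------------------------------------------------------------

def plant_sweep_frequencies(
    p_groups: np.ndarray, selected: int, factor: float, shift: float
) -> np.ndarray:
    """Deform per-group alt-allele frequencies at sweep sites.

    The selected group's minor allele frequency is multiplied by (1-factor),
    pushing it toward the nearest fixation point; every other group is moved
    a fraction ``shift`` of the way toward the opposite allele.
    """
    out = p_groups.copy()
    p_sel = out[selected]
    toward_zero = p_sel <= 0.5
    out[selected] = np.where(toward_zero, p_sel * (1 - factor), 1 - (1 - p_sel) * (1 - factor))
    for g in range(out.shape[0]):
        if g == selected:
            continue
        out[g] = np.where(toward_zero, out[g] + shift * (1 - out[g]), out[g] * (1 - shift))
    return out


def simulate_populations(
    params: PopSimParams, outdir: str | Path, prefix: str = "pop"
) -> dict[str, Path]:
    """Write a VCF, a sample->group map and a truth BED of sweep windows.

    Returns a dict with keys ``vcf``, ``groups``, ``truth_bed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    n_sites = int(round(params.snp_density * params.chrom_len))
    if n_sites > params.chrom_len:
        raise SimulationParameterError("snp_density implies more SNPs than base pairs")
    positions = np.sort(
        rng.choice(params.chrom_len, size=n_sites, replace=False)
    )  # 0-based; +1 when written

    p_anc = rng.beta(params.beta_alpha, params.beta_beta, size=n_sites)
    # binomial resample per group -> mild background differentiation
    p_groups = (
        rng.binomial(params.resample_n, p_anc[None, :].repeat(params.n_groups, axis=0))
        / params.resample_n
    )

    sweep_map = dict(params.sweep_windows)
    window_of_site = positions // params.window_len
    for w, g in sweep_map.items():
        in_w = window_of_site == w
        if in_w.any():
            p_groups[:, in_w] = plant_sweep_frequencies(
                p_groups[:, in_w],
                g,
                params.sweep_diversity_factor,
                params.sweep_divergence_shift,
            )

    # two independent haploid draws per diploid sample
    n_per = params.samples_per_group
    samples = [f"{grp}_s{i}" for grp in params.group_names for i in range(n_per)]
    hap = np.empty((n_sites, 2 * len(samples)), dtype=np.int8)
    for gi in range(params.n_groups):
        cols = slice(2 * gi * n_per, 2 * (gi + 1) * n_per)
        hap[:, cols] = rng.random((n_sites, 2 * n_per)) < p_groups[gi][:, None]

    ref = _random_seq(rng, n_sites)
    alt = (ref + rng.integers(1, 4, size=n_sites)) % 4

    vcf_path = outdir / f"{prefix}.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={params.chrom},length={params.chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(n_sites):
            gts = "\t".join(
                f"{hap[j, 2 * i]}/{hap[j, 2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{params.chrom}\t{positions[j] + 1}\t.\t{DNA[ref[j]]}\t{DNA[alt[j]]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )

    groups_path = outdir / f"{prefix}.groups.tsv"
    with open(groups_path, "w") as fh:
        for gi, grp in enumerate(params.group_names):
            for i in range(n_per):
                fh.write(f"{grp}_s{i}\t{grp}\n")

    bed_path = outdir / f"{prefix}.sweeps.bed"
    with open(bed_path, "w") as fh:
        for w in sorted(sweep_map):
            g = sweep_map[w]
            fh.write(
                f"{params.chrom}\t{w * params.window_len}\t{(w + 1) * params.window_len}"
                f"\t{params.group_names[g]}\n"
            )

    return {"vcf": vcf_path, "groups": groups_path, "truth_bed": bed_path}


# ---------------------------------------------------------------------------
# LTR element generator
# ---------------------------------------------------------------------------

def _age_group_index(age_years: float) -> int:
    """0: <0.2 My, 1: 0.2-1 My, 2: >1 My (same partition as the dater)."""
    if age_years < 2e5:
        return 0
    if age_years <= 1e6:
        return 1
    return 2


def simulate_ltr_elements(
    params: LTRSimParams, outdir: str | Path, prefix: str = "ltr"
) -> dict[str, Path]:
    """Write an element FASTA, a truth table and a placements BED.

    The truth table carries, per element, the planted age, the age group and
    the 5'/3' LTR coordinates within the FASTA record (0-based half-open),
    which is the input contract of the dating stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    ages = np.asarray(params.ages, dtype=float)
    age_of = ages[rng.integers(0, len(ages), size=params.n_elements)]

    cs, ce = params.centromere_interval
    elen = params.element_len
    records: list[tuple[str, str]] = []
    truth_rows: list[str] = []
    bed_rows: list[tuple[int, str]] = []
    for i in range(params.n_elements):
        age = age_of[i]
        anc = _random_seq(rng, params.ltr_len)
        p_sub = min(params.rate * age, 0.75)
        ltr5 = _mutate_subs(rng, anc, p_sub)
        ltr3 = _mutate_subs(rng, anc, p_sub)
        internal = _random_seq(rng, params.internal_len)
        seq = _to_str(np.concatenate([ltr5, internal, ltr3]))
        name = f"LTRRT_{i:05d}"
        records.append((name, seq))

        grp = _age_group_index(age)
        p_cen = params.centromere_placement_prob_by_age_group[grp]
        if rng.random() < p_cen:
            start = int(rng.integers(cs, max(cs + 1, ce - elen)))
        else:
            # uniform over the two arms, proportional to arm length
            left = cs - elen
            right_lo, right_hi = ce, params.chrom_len - elen
            total = max(left, 0) + max(right_hi - right_lo, 0)
            u = int(rng.integers(0, max(total, 1)))
            start = u if u < max(left, 0) else right_lo + (u - max(left, 0))
        truth_rows.append(
            f"{name}\t{age:.0f}\t{grp}\t0\t{params.ltr_len}"
            f"\t{params.ltr_len + params.internal_len}\t{elen}\n"
        )
        bed_rows.append((start, f"{params.chrom}\t{start}\t{start + elen}\t{name}\n"))

    fasta_path = outdir / f"{prefix}.elements.fasta"
    write_fasta(fasta_path, records)

    truth_path = outdir / f"{prefix}.truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("id\tage_years\tage_group_index\tltr5_start\tltr5_end\tltr3_start\tltr3_end\n")
        fh.writelines(truth_rows)

    bed_path = outdir / f"{prefix}.placements.bed"
    with open(bed_path, "w") as fh:
        fh.writelines(row for _, row in sorted(bed_rows))

    cen_path = outdir / f"{prefix}.centromere.bed"
    with open(cen_path, "w") as fh:
        fh.write(f"{params.chrom}\t{cs}\t{ce}\n")

    return {
        "fasta": fasta_path,
        "truth": truth_path,
        "placements": bed_path,
        "centromere_bed": cen_path,
    }


# ---------------------------------------------------------------------------
# satellite array generator
# ---------------------------------------------------------------------------

def simulate_tandem_array_genome(
    params: SatelliteSimParams, outdir: str | Path, prefix: str = "sat"
) -> dict[str, Path]:
    """Write a chromosome FASTA with one planted tandem array plus truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    monomer = _random_seq(rng, params.monomer_len)
    copies = []
    for _ in range(params.n_copies):
        c = _mutate_subs(rng, monomer, params.substitution_rate_per_site)
        if params.indel_rate > 0:
            keep = rng.random(len(c)) >= params.indel_rate  # 1-bp deletions
            c = c[keep]
            ins = rng.random(len(c)) < params.indel_rate  # 1-bp insertions
            if ins.any():
                parts = []
                for i, b in enumerate(c):
                    parts.append(b)
                    if ins[i]:
                        parts.append(rng.integers(0, 4))
                c = np.asarray(parts)
        copies.append(c)
    array = np.concatenate(copies) if copies else np.empty(0, dtype=int)
    left = _random_seq(rng, params.flank_len)
    right = _random_seq(rng, params.flank_len)
    chrom_seq = _to_str(np.concatenate([left, array, right]))

    fasta_path = outdir / f"{prefix}.fasta"
    write_fasta(fasta_path, [(params.chrom, chrom_seq)])

    truth_bed = outdir / f"{prefix}.truth.bed"
    with open(truth_bed, "w") as fh:
        fh.write(f"{params.chrom}\t{params.flank_len}\t{params.flank_len + len(array)}\n")

    monomer_path = outdir / f"{prefix}.monomer.txt"
    with open(monomer_path, "w") as fh:
        fh.write(_to_str(monomer) + "\n")

    return {"fasta": fasta_path, "truth_bed": truth_bed, "monomer": monomer_path}


# ---------------------------------------------------------------------------
# gene annotation generator
# ---------------------------------------------------------------------------

def simulate_gene_annotation(
    params: AnnotSimParams, outdir: str | Path, prefix: str = "annot"
) -> dict[str, Path]:
    """Write a GFF3 with planted head-to-head NLR pairs plus truth tables.

    Layout: features are placed left to right with random intergenic gaps.
    The first 2*n_pairs NLR ids form head-to-head pairs ('-' gene then '+'
    gene separated by exactly ``pair_intergenic_dist``); remaining NLRs and
    ordinary genes are isolated or tandem-same-strand.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    glen = params.gene_len
    n_single = params.n_genes - 2 * params.n_pairs
    # required span: every gene + pair gaps + minimal 200bp spacers
    min_span = params.n_genes * glen + params.n_pairs * params.pair_intergenic_dist + 200 * (
        params.n_genes + 1
    )
    if min_span > params.chrom_len:
        raise PlacementError(
            f"cannot place {params.n_genes} genes of {glen} bp on {params.chrom_len} bp"
        )

    # unit list: pairs first, then singles; shuffle order along the chromosome
    units: list[tuple[str, int]] = [("pair", i) for i in range(params.n_pairs)]
    units += [("single", i) for i in range(n_single)]
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    slack = params.chrom_len - min_span
    n_gaps = len(units) + 1
    gaps = 200 + rng.multinomial(slack, np.full(n_gaps, 1 / n_gaps))

    nlr_ids: list[str] = []
    pair_rows: list[str] = []
    genes: list[tuple[str, int, int, str]] = []  # id, start(1-based), end, strand
    pair_seen = 0
    single_seen = 0
    pos = 0
    gi = 0
    for ui, (kind, _) in enumerate(units):
        pos += int(gaps[ui])
        if kind == "pair":
            a_id, b_id = f"gene{gi:04d}", f"gene{gi + 1:04d}"
            gi += 2
            a = (a_id, pos + 1, pos + glen, "-")
            b_start = pos + glen + params.pair_intergenic_dist
            b = (b_id, b_start + 1, b_start + glen, "+")
            genes += [a, b]
            nlr_ids += [a_id, b_id]
            pair_rows.append(f"{a_id}\t{b_id}\t{params.pair_intergenic_dist}\n")
            pos = b_start + glen
            pair_seen += 1
        else:
            g_id = f"gene{gi:04d}"
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((g_id, pos + 1, pos + glen, strand))
            # non-pair NLRs: keep same-strand so they can never be head-to-head
            if single_seen < params.n_nlr - 2 * params.n_pairs:
                nlr_ids.append(g_id)
                genes[-1] = (g_id, pos + 1, pos + glen, "+")
            pos += glen
            single_seen += 1

    gff_path = outdir / f"{prefix}.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {params.chrom} 1 {params.chrom_len}\n")
        for g_id, start, end, strand in genes:
            fh.write(
                f"{params.chrom}\tnapustools_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={g_id}\n"
            )
            fh.write(
                f"{params.chrom}\tnapustools_sim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={g_id}.t1;Parent={g_id}\n"
            )
            fh.write(
                f"{params.chrom}\tnapustools_sim\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                f"ID={g_id}.cds;Parent={g_id}.t1\n"
            )

    pairs_path = outdir / f"{prefix}.pairs.tsv"
    with open(pairs_path, "w") as fh:
        fh.write("gene_a\tgene_b\tintergenic_dist\n")
        fh.writelines(pair_rows)

    nlr_path = outdir / f"{prefix}.nlr_ids.txt"
    with open(nlr_path, "w") as fh:
        fh.writelines(i + "\n" for i in sorted(nlr_ids))

    return {"gff3": gff_path, "pairs": pairs_path, "nlr_ids": nlr_path}
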