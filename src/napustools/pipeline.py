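"""Pipeline orchestration, configuration and assembly-summary arithmetic.

A single YAML config drives all stages (simulation, sweep scan, effect
classification, LTR dating, centromere detection, NLR pairing); every
output file carries the config hash in a header line so a run directory
is self-describing, and identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from . import sweeps, variants

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_anchoring", "AnchoringSummary"]


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream output."""


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "scan", "report")
    # simulation
    n_groups: int = 2
    samples_per_group: int = 20
    n_windows: int = 50
    window_len: int = 20_000
    snp_density: float = 0.005
    sweep_windows: tuple[tuple[int, int], ...] = ((25, 0),)
    sweep_diversity_factor: float = 0.9
    sweep_divergence_shift: float = 0.6
    # scan
    window: int = 20_000
    step: int = 20_000
    q_fst: float = 0.05
    q_pi: float = 0.05
    # external inputs when not simulating
    vcf: str | None = None
    groups_tsv: str | None = None
    gff3: str | None = None
    qtl_bed: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", ()))
        raw["sweep_windows"] = tuple(tuple(x) for x in raw.get("sweep_windows", ()))
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(path: Path, hash_: str) -> None:
    """Prepend the config hash as a comment header."""
    text = path.read_text()
    path.write_text(f"# config_hash={hash_}\n" + text)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the enabled stages in dependency order; return output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    outputs: dict[str, Path] = {}
    config.to_yaml(outdir / "config.yaml")

    vcf, groups_tsv = config.vcf, config.groups_tsv
    if "simulate" in config.stages:
        params = sim.PopSimParams(
            n_groups=config.n_groups,
            samples_per_group=config.samples_per_group,
            n_windows=config.n_windows,
            window_len=config.window_len,
            snp_density=config.snp_density,
            sweep_windows=config.sweep_windows,
            sweep_diversity_factor=config.sweep_diversity_factor,
            sweep_divergence_shift=config.sweep_divergence_shift,
            seed=config.seed,
        )
        paths = sim.simulate_populations(params, outdir)
        vcf, groups_tsv = str(paths["vcf"]), str(paths["groups"])
        outputs.update(paths)

    if "scan" in config.stages:
        if vcf is None or groups_tsv is None:
            raise DependencyError("scan stage requires a VCF and group map "
                                  "(enable 'simulate' or set vcf/groups_tsv)")
        matrix = variants.load_genotypes(vcf, groups_tsv)
        group_names = sorted(set(matrix.sample_groups.values()))
        chrom_lengths = {
            str(c): config.n_windows * config.window_len for c in pd.unique(matrix.chrom)
        }
        stats = sweeps.scan_windows(
            matrix, group_names[0], group_names[1],
            window=config.window, step=config.step, chrom_lengths=chrom_lengths,
        )
        windows_path = outdir / "windows.tsv"
        stats.to_csv(windows_path, sep="\t", index=False)
        _stamp(windows_path, h)
        outputs["windows"] = windows_path

        regions = sweeps.call_sweeps(
            stats, group_names[0], group_names[1], q_fst=config.q_fst, q_pi=config.q_pi
        )
        if config.gff3:
            regions = sweeps.overlap_annotations(regions, gff3=config.gff3,
                                                 qtl_bed=config.qtl_bed)
        bed_path = outdir / "regions.bed"
        with open(bed_path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.selected_group}\n")
        _stamp(bed_path, h)
        tsv_path = outdir / "regions.tsv"
        sweeps.regions_to_frame(regions).to_csv(tsv_path, sep="\t", index=False)
        _stamp(tsv_path, h)
        outputs["regions_bed"] = bed_path
        outputs["regions_tsv"] = tsv_path

    if "report" in config.stages:
        if "regions_bed" not in outputs and "scan" in config.stages:
            raise DependencyError("report stage requires the scan stage outputs")
        log_path = outdir / "run_log.json"
        with open(log_path, "w") as fh:
            json.dump(
                {"config_hash": h, "outputs": {k: str(v) for k, v in outputs.items()}},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        outputs["run_log"] = log_path
    return outputs


# ---------------------------------------------------------------------------
# anchoring arithmetic
# ---------------------------------------------------------------------------

@dataclass
class AnchoringSummary:
    anchored_total: float
    assembly_total: float
    anchored_percent: float
    subgenome_totals: dict[str, float] = field(default_factory=dict)
    subgenome_percents: dict[str, float] = field(default_factory=dict)


def _pct1(x: float, total: float) -> float:
    return float(
        (Decimal(100) * Decimal(str(x)) / Decimal(str(total))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_anchoring(
    chromosome_lengths: dict[str, float], assembly_total: float
) -> AnchoringSummary:
    """Anchored fraction of an assembly, overall and per subgenome.

    Chromosome names beginning with 'A' or 'C' (case-insensitive, e.g.
    A01..A10, C01..C09) are grouped into subgenomes; anything else counts
    toward the anchored total only.  Percentages are of ``assembly_total``,
    rounded half-up to one decimal.
    """
    if any(v <= 0 for v in chromosome_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    anchored = float(sum(chromosome_lengths.values()))
    if anchored > assembly_total:
        raise ValueError("anchored length exceeds assembly total")
    sub_tot: dict[str, float] = {}
    for name, length in chromosome_lengths.items():
        prefix = name.lstrip("chr")[:1].upper()
        key = prefix if prefix in ("A", "C") else "scaffold"
        sub_tot[key] = sub_tot.get(key, 0.0) + float(length)
    return AnchoringSummary(
        anchored_total=anchored,
        assembly_total=float(assembly_total),
        anchored_percent=_pct1(anchored, assembly_total),
        subgenome_totals=sub_tot,
        subgenome_percents={k: _pct1(v, assembly_total) for k, v in sub_tot.items()},
    )
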