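"""End-to-end pipeline orchestration and reproducibility plumbing.

A run is described by a flat key→value configuration (JSON file and/or
CLI overrides; precedence CLI > config > defaults).  The pipeline scans
or loads per-sample tallies, applies the artifact filters, aggregates to
the coarse grid, computes leave-one-out regional differences, calibrates
scores, evaluates, and writes every artifact with checksums and a config
snapshot so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome as gn
from . import regional, scoring
from .filters import PopulationSites, filter_oxog, population_filter, estimate_oxog
from .scan import BinTallyMatrix, QualityConfig, scan_alignments

log = logging.getLogger("gemini")

_CONFIG_FIELDS = {
    "sample_sheet", "build", "bin_width", "aggregation_factor", "mode",
    "min_mapq", "min_base_q", "mutation_type", "oxog_policy",
    "population_vcf", "mask_bed", "reference", "specificity", "outdir",
    "seed", "log_level",
}


@dataclass
class RunConfig:
    sample_sheet: str = ""
    build: str = "hg19"  # "hg19" or a TSV of chrom<TAB>length
    bin_width: int = 100_000
    aggregation_factor: int = 25
    mode: str = "plasma"
    min_mapq: int = 40
    min_base_q: int = 30
    mutation_type: str = "C>A"
    oxog_policy: str = "drop_pyr_r2"
    population_vcf: str = ""
    mask_bed: str = ""
    reference: str = ""
    specificity: float = 0.8
    outdir: str = "gemini_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | None = None, **overrides) -> "RunConfig":
        """Config file plus explicit overrides; unknown keys are rejected."""
        values: dict = {}
        if path:
            with open(path) as fh:
                values.update(json.load(fh))
        values.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(values) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)


def load_build(spec: str) -> gn.GenomeBuild:
    if spec == "hg19":
        return gn.GenomeBuild.hg19_autosomes()
    df = pd.read_csv(spec, sep="\t", header=None, names=["chrom", "length"])
    return gn.GenomeBuild(os.path.basename(spec),
                          tuple(zip(df["chrom"], df["length"].astype(int))))


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_or_scan(row, bins, mask, qc, cfg) -> tuple[BinTallyMatrix, dict]:
    path = row["path"]
    if path.endswith(".tsv"):
        log.info("loading precomputed tally %s", path)
        return BinTallyMatrix.from_tsv(path), {}
    tally, candidates = scan_alignments(
        path, cfg.reference, bins, mask, qc, sample_id=row["id"]
    )
    if cfg.population_vcf:
        sites = PopulationSites.from_vcf(cfg.population_vcf)
        candidates, tally = population_filter(candidates, sites, tally)
    return tally, {"n_candidates_after_filters": len(candidates)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute scan → filter → aggregate → LOOCV → calibrate → evaluate.

    Returns a dict of artifact paths; raises with stage and sample context
    on failure.
    """
    logging.basicConfig(level=cfg.log_level)
    os.makedirs(cfg.outdir, exist_ok=True)
    sheet = pd.read_csv(cfg.sample_sheet, sep="\t", dtype={"id": str})
    for col in ("id", "path", "label"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    build = load_build(cfg.build)
    bins = gn.make_bins(build, cfg.bin_width, scope="all")
    mask = gn.MaskTrack.from_bed(cfg.mask_bed) if cfg.mask_bed else gn.MaskTrack([])
    qc = QualityConfig(min_mapq=cfg.min_mapq, min_base_q=cfg.min_base_q, mode=cfg.mode)

    tallies, extras = [], []
    for _, row in sheet.iterrows():
        try:
            tally, extra = _load_or_scan(row, bins, mask, qc, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage=scan sample={row['id']}: {exc}") from exc
        tally, _ = filter_oxog(tally, policy=cfg.oxog_policy)
        tallies.append(tally)
        extras.append(extra)
    labels = sheet["label"].astype(int).to_numpy()

    coarse_bins, index_map = gn.aggregate_bins(bins, cfg.aggregation_factor)
    coarse = [t.aggregate(coarse_bins, index_map) for t in tallies]

    try:
        rds, folds = regional.loocv_regional_differences(coarse, labels, cfg.mutation_type)
    except Exception as exc:
        raise RuntimeError(f"stage=cv: {exc}") from exc
    rd_values = np.array([r.value for r in rds])
    b0, b1 = scoring.fit_calibration(rd_values, labels)
    scores = 1.0 / (1.0 + np.exp(-(b0 + b1 * rd_values)))

    # frozen full-cohort model for application to unseen samples
    full_delta = regional.pooled_delta(coarse, labels, cfg.mutation_type)
    full_sets = regional.select_decile_bins(full_delta, fold_id="full")
    model = scoring.GeminiModel(
        cfg.mutation_type, full_sets, b0, b1,
        grid_checksum=regional.grid_checksum(coarse_bins),
        provenance={"train_ids": list(sheet["id"]), "n": len(sheet)},
    )

    auc = scoring.roc_auc(scores, labels)
    cutoff, sens = scoring.threshold_at_specificity(scores, labels, cfg.specificity)

    score_table = pd.DataFrame(
        {
            "sample_id": sheet["id"],
            "label": labels,
            "regional_difference": rd_values,
            "gemini_score": scores,
            "oxog_ratio": [estimate_oxog(t).ratio for t in tallies],
        }
    )
    paths = {
        "scores": os.path.join(cfg.outdir, "scores.tsv"),
        "model": os.path.join(cfg.outdir, "model.json"),
        "audit": os.path.join(cfg.outdir, "audit.json"),
    }
    score_table.to_csv(paths["scores"], sep="\t", index=False, float_format="%.10g")
    model.to_json(paths["model"])
    audit = {
        "config": dataclasses.asdict(cfg),
        "stability": regional.fold_stability(folds),
        "auc": auc.auc,
        "auc_ci": [auc.ci_low, auc.ci_high],
        "cutoff_at_specificity": cutoff,
        "sensitivity_at_specificity": sens,
        "filter_logs": [t.metadata.get("filter_log", []) for t in tallies],
        "scan_extras": extras,
        "checksums": {k: _checksum(p) for k, p in paths.items() if k != "audit"},
    }
    with open(paths["audit"], "w") as fh:
        json.dump(audit, fh, indent=1, sort_keys=True, default=str)
    return paths


# --------------------------------------------------------------------------
# Fixture bundle: tiny deterministic FASTA/SAM/VCF/BED/TSV inputs
# --------------------------------------------------------------------------

def make_fixture_bundle(seed: int, outdir: str) -> dict:
    """Write a small deterministic end-to-end fixture directory.

    Two toy chromosomes, planted somatic/germline/oxo-dG/doublet events,
    a mask, a population VCF carrying the germline site, a build TSV and
    a sample sheet — everything the pipeline needs, regenerable from the
    seed alone.
    """
    from .simulate import PlannedVariant, random_genome, simulate_reads

    os.makedirs(outdir, exist_ok=True)
    lengths = {"chr1": 60_000, "chr2": 40_000}
    genome = random_genome(lengths, seed=seed)

    def find_base(chrom, base, lo, offset=0):
        pos = genome[chrom].find(base, lo)
        if pos < 0:
            raise RuntimeError("fixture genome lacks required base")
        return pos + offset

    germline = [
        PlannedVariant("chr1", find_base("chr1", "T", lo), "C", 1.0, "germline")
        for lo in (12_000, 20_000, 28_000, 36_000, 44_000, 52_000)
    ] + [
        PlannedVariant("chr2", find_base("chr2", "A", lo), "G", 1.0, "germline")
        for lo in (5_000, 15_000, 25_000, 35_000)
    ]
    plan = germline + [
        PlannedVariant("chr1", find_base("chr1", "C", 5_000), "A", 0.10, "somatic"),
        PlannedVariant("chr2", find_base("chr2", "G", 8_000), "T", 0.08, "oxog"),
        PlannedVariant("chr2", find_base("chr2", "CC", 15_000), "AA", 0.10, "doublet"),
    ]
    rows = []
    for i, label in enumerate([1, 1, 0, 0]):
        prefix = os.path.join(outdir, f"s{i}")
        sim_plan = plan if label else [v for v in plan if v.kind != "somatic"]
        simulate_reads(genome, sim_plan, n_pairs=1500, out_prefix=prefix,
                       seed=seed * 100 + i, sample_id=f"s{i}")
        rows.append({"id": f"s{i}", "path": f"{prefix}.sam", "label": label})

    build_tsv = os.path.join(outdir, "build.tsv")
    with open(build_tsv, "w") as fh:
        for c, n in lengths.items():
            fh.write(f"{c}\t{n}\n")
    mask_bed = os.path.join(outdir, "mask.bed")
    with open(mask_bed, "w") as fh:
        fh.write("chr1\t0\t1000\n")
    pop_vcf = os.path.join(outdir, "population.vcf")
    with open(pop_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="allele frequency">\n')
        for c, n in lengths.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for g in sorted(germline, key=lambda v: (v.chrom, v.pos)):
            ref = genome[g.chrom][g.pos]
            fh.write(f"{g.chrom}\t{g.pos + 1}\t.\t{ref}\t{g.alt}\t.\tPASS\tAF=0.01\n")
    sheet = os.path.join(outdir, "samples.tsv")
    pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
    config = os.path.join(outdir, "config.json")
    with open(config, "w") as fh:
        json.dump(
            {
                "sample_sheet": sheet,
                "build": build_tsv,
                "bin_width": 10_000,
                "aggregation_factor": 1,
                "mode": "plasma",
                "reference": os.path.join(outdir, "s0.fa"),
                "mask_bed": mask_bed,
                "population_vcf": pop_vcf,
                "outdir": os.path.join(outdir, "out"),
                "seed": seed,
            },
            fh, indent=1,
        )
    return {"sheet": sheet, "config": config, "build": build_tsv,
            "mask": mask_bed, "population_vcf": pop_vcf}
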