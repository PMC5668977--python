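"""End-to-end orchestration: simulate -> preprocess -> discover -> express
-> target, from a single YAML config, with deterministic outputs, per-stage
logging and a manifest of checksummed artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import read_fasta, sha256_file
from .preprocess import PreprocessResult, preprocess_libraries, stats_table
from .discovery import (
    DiscoveryResult,
    HairpinCriteria,
    catalog_table,
    discover_mirnas,
    write_precursor_fasta,
    write_precursor_gff3,
)
from .expression import (
    Contrast,
    ExpressionMatrix,
    build_matrix,
    call_differential,
    composition_stats,
    de_overlap_table,
    de_table,
    replicate_correlation,
    tissue_specificity,
)
from .targeting import score_targets, target_table

log = logging.getLogger("heatmir")


class ConfigError(ValueError):
    pass


@dataclass
class LibraryEntry:
    library_id: str
    fastq: str
    tissue: str
    condition: str
    timepoint: str
    replicate: int


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    genome: str
    contaminants: str
    reference: str
    libraries: list[LibraryEntry]
    output_dir: str
    transcripts: str | None = None
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 15
    max_len: int = 40
    min_tpm: float = 10.0
    len_range: tuple[int, int] = (18, 30)
    max_hits: int = 20
    flank: int = 200
    mfe_max: float = -16.0
    de_log2fc: float = 1.0
    de_p: float = 0.05
    target_cutoff: float = 3.0
    engine: str = "builtin"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        for key in ("genome", "contaminants", "reference", "libraries", "output_dir"):
            if key not in raw:
                raise ConfigError(f"config missing required field {key!r}")
        libs = [LibraryEntry(**entry) for entry in raw.pop("libraries")]
        if "len_range" in raw:
            raw["len_range"] = tuple(raw["len_range"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(libraries=libs, **raw)

    def validate(self) -> None:
        """Check every referenced file before any computation starts."""
        for attr in ("genome", "contaminants", "reference"):
            path = getattr(self, attr)
            if not Path(path).is_file():
                raise ConfigError(f"config field {attr!r}: file not found: {path}")
        if self.transcripts is not None and not Path(self.transcripts).is_file():
            raise ConfigError(
                f"config field 'transcripts': file not found: {self.transcripts}"
            )
        if not self.libraries:
            raise ConfigError("config field 'libraries' is empty")
        for lib in self.libraries:
            if not Path(lib.fastq).is_file():
                raise ConfigError(
                    f"library {lib.library_id!r}: fastq not found: {lib.fastq}"
                )
        if not 0 < self.de_p <= 1:
            raise ConfigError("de_p must be in (0, 1]")
        if self.min_tpm < 0 or self.max_hits < 1 or self.flank < 0:
            raise ConfigError("thresholds out of range")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    stage_counts: dict = field(default_factory=dict)
    catalog: dict = field(default_factory=dict)
    de_summary: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResults:
    config: PipelineConfig
    preprocess: PreprocessResult
    discovery: DiscoveryResult
    matrix: ExpressionMatrix
    de_results: dict[str, list]
    correlations: pd.DataFrame
    specificity: pd.DataFrame
    target_sites: list
    report: RunReport


def default_contrasts(libraries: list[LibraryEntry]) -> list[Contrast]:
    """One HS-vs-CK contrast per (tissue, timepoint) with pooled replicates."""
    contrasts = []
    tissues = sorted({l.tissue for l in libraries})
    timepoints = sorted({l.timepoint for l in libraries})
    for tissue in tissues:
        for tp in timepoints:
            hs = tuple(
                l.library_id
                for l in libraries
                if l.tissue == tissue and l.timepoint == tp and l.condition == "HS"
            )
            ck = tuple(
                l.library_id
                for l in libraries
                if l.tissue == tissue and l.timepoint == tp and l.condition == "CK"
            )
            if hs and ck:
                contrasts.append(
                    Contrast(name=f"{tissue}_{tp}_HS_vs_CK", libs_a=hs, libs_b=ck)
                )
    return contrasts


def replicate_pairs(libraries: list[LibraryEntry]) -> list[tuple[str, str]]:
    pairs = []
    keyed: dict[tuple, list[str]] = {}
    for l in libraries:
        keyed.setdefault((l.tissue, l.condition, l.timepoint), []).append(l.library_id)
    for _key, libs in sorted(keyed.items()):
        libs = sorted(libs)
        if len(libs) >= 2:
            pairs.append((libs[0], libs[1]))
    return pairs


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run all stages, writing each stage's artifacts as soon as it completes."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    report = RunReport(
        seed=config.seed, config_hash=config.config_hash(), version=__version__
    )
    manifest: dict[str, str] = {}
    header = f"# heatmir {__version__} seed={config.seed} config={report.config_hash}"

    def _emit(name: str, df: pd.DataFrame, index: bool) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", index=index)
        manifest[name] = sha256_file(path)

    t0 = time.time()
    log.info("stage preprocess: %d libraries", len(config.libraries))
    fastq_map = {l.library_id: l.fastq for l in config.libraries}
    try:
        pre = preprocess_libraries(
            fastq_map,
            config.adapter3,
            config.contaminants,
            min_len=config.min_len,
            max_len=config.max_len,
        )
    except Exception:
        log.exception("stage preprocess failed")
        raise
    report.timings_s["preprocess"] = round(time.time() - t0, 2)
    report.stage_counts["raw_reads"] = int(sum(s.raw_reads for s in pre.stats))
    report.stage_counts["after_trim_filter"] = int(
        sum(s.after_trim_filter for s in pre.stats)
    )
    report.stage_counts["contaminant_reads"] = int(
        sum(s.contaminant_reads for s in pre.stats)
    )
    report.stage_counts["clean_reads"] = int(sum(s.clean_reads for s in pre.stats))
    report.stage_counts["unique_tags"] = int(len(pre.counts))
    _emit("library_stats.tsv", stats_table(pre.stats), index=True)
    if len(pre.removed_by_class):
        _emit("contaminant_classes.tsv", pre.removed_by_class, index=True)

    t0 = time.time()
    log.info("stage discovery")
    genome = read_fasta(config.genome)
    genome = {name.split()[0]: seq for name, seq in genome.items()}
    try:
        disc = discover_mirnas(
            pre.tpm,
            genome,
            config.reference,
            min_tpm=config.min_tpm,
            len_range=config.len_range,
            max_hits=config.max_hits,
            flank=config.flank,
            mfe_max=config.mfe_max,
            criteria=HairpinCriteria(),
            engine=config.engine,
        )
    except Exception:
        log.exception("stage discovery failed")
        raise
    report.timings_s["discovery"] = round(time.time() - t0, 2)
    report.stage_counts["prefiltered_tags"] = disc.n_prefiltered
    report.stage_counts["candidate_tags"] = disc.n_candidates
    report.stage_counts["hairpin_pass"] = disc.n_hairpin_pass
    report.catalog = {
        "known": len(disc.known),
        "novel": len(disc.novel),
        "families": len(disc.families),
    }
    cand_counts = pre.counts.loc[pre.counts.index.isin(
        {r.mature_seq for r in disc.records}
    )]
    _emit("catalog.tsv", catalog_table(disc.records), index=False)
    _emit("candidate_tag_counts.tsv", cand_counts, index=True)
    gff_path = outdir / "precursors.gff3"
    write_precursor_gff3(disc.records, gff_path)
    manifest["precursors.gff3"] = sha256_file(gff_path)
    fa_path = outdir / "precursors.fasta"
    write_precursor_fasta(disc.records, fa_path)
    manifest["precursors.fasta"] = sha256_file(fa_path)

    t0 = time.time()
    log.info("stage expression")
    matrix = build_matrix(disc.records, pre.counts, pre.clean_totals)
    de_results: dict[str, list] = {}
    for contrast in default_contrasts(config.libraries):
        de_results[contrast.name] = call_differential(
            matrix, contrast, log2fc_min=config.de_log2fc, p_max=config.de_p
        )
    all_de = [r for rs in de_results.values() for r in rs]
    corr = replicate_correlation(matrix.tpm, replicate_pairs(config.libraries))
    tissues: dict[str, tuple[str, ...]] = {}
    for l in config.libraries:
        if l.condition == "CK":
            tissues.setdefault(l.tissue, ())
            tissues[l.tissue] += (l.library_id,)
    spec_df = (
        tissue_specificity(matrix, tissues, min_tpm=config.min_tpm)
        if len(tissues) == 2
        else pd.DataFrame()
    )
    comp = composition_stats(matrix.counts)
    report.timings_s["expression"] = round(time.time() - t0, 2)
    for cname, rs in de_results.items():
        report.de_summary[cname] = {
            "up": sum(1 for r in rs if r.call == "up"),
            "down": sum(1 for r in rs if r.call == "down"),
            "ns": sum(1 for r in rs if r.call == "ns"),
        }
    _emit("expression_counts.tsv", matrix.counts, index=True)
    _emit("expression_tpm.tsv", matrix.tpm.round(3), index=True)
    _emit("de_results.tsv", de_table(all_de), index=False)
    _emit("de_overlap.tsv", de_overlap_table(de_results), index=True)
    _emit("replicate_correlation.tsv", corr, index=False)
    if len(spec_df):
        _emit("tissue_specificity.tsv", spec_df, index=True)
    _emit("length_distribution.tsv", comp.length_dist, index=True)
    _emit("first_nt.tsv", comp.first_nt, index=True)
    _emit("positional_composition.tsv", comp.positional.round(4), index=True)

    sites: list = []
    if config.transcripts is not None:
        t0 = time.time()
        log.info("stage targeting")
        de_mirnas = sorted({r.mirna for r in all_de if r.call != "ns"})
        by_name = {r.name: r for r in disc.records}
        for name in de_mirnas:
            rec = by_name.get(name)
            if rec is None:
                continue
            sites.extend(
                score_targets(
                    rec.mature_seq,
                    config.transcripts,
                    cutoff=config.target_cutoff,
                    mirna_name=name,
                )
            )
        report.timings_s["targeting"] = round(time.time() - t0, 2)
        report.stage_counts["target_sites"] = len(sites)
        _emit("targets.tsv", target_table(sites), index=False)

    report_path = outdir / "run_report.json"
    report_path.write_text(report.to_json() + "\n")
    manifest["run_report.json"] = sha256_file(report_path)
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write(header + "\nfile\tsha256\n")
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    log.info("pipeline complete: %s", outdir)
    return PipelineResults(
        config=config,
        preprocess=pre,
        discovery=disc,
        matrix=matrix,
        de_results=de_results,
        correlations=corr,
        specificity=spec_df,
        target_sites=sites,
        report=report,
    )


def verify_manifest(outdir: str | Path) -> bool:
    """Re-hash every artifact listed in the manifest."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "manifest.tsv", sep="\t", comment="#")
    return all(
        sha256_file(outdir / row["file"]) == row["sha256"] for _, row in df.iterrows()
    )


def _setup_logging(outdir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("[heatmir %(asctime)s] %(message)s"))
        log.addHandler(stream)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("[%(asctime)s] %(levelname)s %(message)s"))
    log.addHandler(fh)


# ---------------------------------------------------------------------------
# bundled synthetic demo
# ---------------------------------------------------------------------------


def simulate_to_config(
    outdir: str | Path, seed: int, depth: int = 200_000, **dataset_kwargs
) -> Path:
    """Generate the default synthetic dataset under ``outdir`` and write a
    ready-to-run pipeline config YAML; returns the config path."""
    from .simdata import build_dataset, write_dataset

    outdir = Path(outdir)
    data_dir = outdir / "data"
    dataset = build_dataset(seed, depth=depth, **dataset_kwargs)
    paths = write_dataset(dataset, data_dir, seed)
    cfg = {
        "genome": str(paths["genome"]),
        "contaminants": str(paths["contaminants"]),
        "reference": str(paths["reference"]),
        "transcripts": str(paths["transcripts"]),
        "output_dir": str(outdir / "results"),
        "seed": seed,
        "libraries": [
            {
                "library_id": d.library_id,
                "fastq": str(paths[d.library_id]),
                "tissue": d.tissue,
                "condition": d.condition,
                "timepoint": d.timepoint,
                "replicate": d.replicate,
            }
            for d in dataset.designs
        ],
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path


def run_demo(
    outdir: str | Path,
    seed: int,
    depth: int = 200_000,
    config_overrides: dict | None = None,
    **dataset_kwargs,
):
    """Simulate the bundled synthetic study and run the full pipeline on it.

    Returns (dataset, PipelineResults)."""
    from .simdata import build_dataset, write_dataset

    outdir = Path(outdir)
    dataset = build_dataset(seed, depth=depth, **dataset_kwargs)
    paths = write_dataset(dataset, outdir / "data", seed)
    config = PipelineConfig(
        genome=str(paths["genome"]),
        contaminants=str(paths["contaminants"]),
        reference=str(paths["reference"]),
        transcripts=str(paths["transcripts"]),
        output_dir=str(outdir / "results"),
        seed=seed,
        libraries=[
            LibraryEntry(
                library_id=d.library_id,
                fastq=str(paths[d.library_id]),
                tissue=d.tissue,
                condition=d.condition,
                timepoint=d.timepoint,
                replicate=d.replicate,
            )
            for d in dataset.designs
        ],
    )
    for key, value in (config_overrides or {}).items():
        if not hasattr(config, key):
            raise ConfigError(f"unknown config override {key!r}")
        setattr(config, key, value)
    results = run_pipeline(config)
    return dataset, results
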