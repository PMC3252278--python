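"""End-to-end pipeline driver, configuration, and table ingestion.

One JSON config holds every stage's parameters so the many thresholds of
the analysis (80/20 and 75/25 DMR criteria, the 20% resistance line, the
100-genomic-CpG density-bin floor, 20-bp metagene bins) are auditable in a
single place. All randomness flows from one root seed through named
per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as al
from . import calling as ca
from . import cgi as cg
from . import expression as ex
from . import profiles as pr
from . import simulate as sim
from .genome import write_fastq

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    return int(np.random.default_rng(
        [root_seed, zlib.crc32(name.encode())]).integers(2**31))


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    genome_spec: dict = field(default_factory=dict)
    samples: tuple = ("oocyte", "sperm", "blastocyst")
    protocol: str = "methylc"
    depth: float = 8.0
    failure_rate: float = 0.01
    duplicate_rate: float = 0.0
    trim: tuple = (0, 0)
    n_tags: int = 50_000
    dmr: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        sim.SyntheticGenomeSpec(**{**self.genome_spec, "seed": self.seed})
        for s in self.samples:
            if s not in sim.SAMPLE_LABELS:
                raise ValueError(f"unknown sample {s!r}")
        cg.DmrParams(**self.dmr)
        sim.ReadSimParams(protocol=self.protocol, depth=self.depth,
                          failure_rate=self.failure_rate)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        cfg.samples = tuple(cfg.samples)
        cfg.trim = tuple(cfg.trim)
        return cfg

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def load_cgi_table(path, fmt: str | None = None) -> pd.DataFrame:
    """Load a per-CGI methylation table (TSV or XLSX).

    Expects coordinate columns (chrom, start, end; cgi_id optional) plus at
    least one per-sample percent column. Cells outside [0,100] invalidate
    their row (counted in ``df.attrs['n_rejected']``); missing cells stay
    NaN, i.e. non-informative.
    """
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "tsv")
    if fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"CGI table needs columns {sorted(required)}")
    if "cgi_id" not in df.columns:
        df.insert(0, "cgi_id", [f"cgi{i:05d}" for i in range(len(df))])
    value_cols = [c for c in df.columns
                  if c not in ("cgi_id", "chrom", "start", "end")
                  and not c.endswith("_informative")
                  and pd.api.types.is_numeric_dtype(df[c])]
    bad = pd.Series(False, index=df.index)
    for c in value_cols:
        bad |= df[c].notna() & ((df[c] < 0) | (df[c] > 100))
    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("load_cgi_table: %d row(s) rejected (percent outside "
                    "[0,100])", n_rejected)
    out = df[~bad].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, align, call, profile and classify; write an output bundle.

    Deterministic for a fixed config; stage failures raise
    :class:`PipelineError` naming the stage, with earlier artifacts left on
    disk. Returns a dict of in-memory results plus the manifest.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logpath = out / "pipeline.log"
    loglines = [f"seed={config.seed}", f"config={dataclasses.asdict(config)}"]
    bundle: dict = {}

    def _stage(name):
        loglines.append(f"stage:{name}")
        log.info("pipeline stage %s", name)

    try:
        _stage("genome")
        spec = sim.SyntheticGenomeSpec(**{**config.genome_spec,
                                          "seed": stage_seed(config.seed,
                                                             "genome")})
        genome = sim.generate_genome(spec)
        genome.save(out / "genome")
        bundle["genome"] = genome
    except Exception as e:  # noqa: BLE001
        raise PipelineError("genome", e) from e

    try:
        _stage("index")
        index = al.build_reference_index(genome)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("index", e) from e

    dmr_params = cg.DmrParams(**config.dmr)
    sample_calls: dict[str, ca.CallSet] = {}
    for sample in config.samples:
        stage = f"sample:{sample}"
        try:
            _stage(stage)
            meth = sim.generate_true_methylome(
                genome, sample,
                sim.MethylomeParams(seed=stage_seed(config.seed,
                                                    f"methylome:{sample}")))
            lib = sim.simulate_bisulfite_reads(
                genome, meth, sim.ReadSimParams(
                    protocol=config.protocol, depth=config.depth,
                    failure_rate=config.failure_rate,
                    duplicate_rate=config.duplicate_rate,
                    seed=stage_seed(config.seed, f"reads:{sample}")))
            write_fastq(lib.reads, out / f"{sample}.fastq")
            aln = al.align_reads(lib, index, protocol=config.protocol,
                                 trim=config.trim)
            filt = al.filter_alignments(aln, genome)
            uniq = al.deduplicate_alignments(filt.main)
            calls = ca.tally_cytosines(uniq, genome)
            mito_calls = ca.tally_cytosines(
                al.deduplicate_alignments(filt.mito), genome) \
                if len(filt.mito) else None
            loglines.append(f"{sample}: filters={filt.counters}")
            conv = ca.estimate_conversion_failure(calls)
            cov = ca.summarize_coverage(calls, genome)
            loglines.append(
                f"{sample}: lambda_failure={conv.failure_rate} "
                f"coverage_ge1={cov.fraction_ge1:.3f} depth={cov.mean_depth:.2f}")
            calls.write_tsv(out / f"{sample}.calls.tsv", contexts=("CpG",))
            calls.write_bedgraph(out / f"{sample}.CpG.bedGraph")
            pr.methylation_level_histogram(calls).to_csv(
                out / f"{sample}.hist.tsv", sep="\t", index=False)
            pr.window_methylation_track(calls).to_csv(
                out / f"{sample}.10kb.tsv", sep="\t", index=False)
            pr.density_methylation_curve(calls).to_csv(
                out / f"{sample}.density.tsv", sep="\t", index=False)
            sample_calls[sample] = calls
            bundle[f"conversion:{sample}"] = conv
            bundle[f"coverage:{sample}"] = cov
            if mito_calls is not None:
                bundle[f"mito:{sample}"] = mito_calls
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    try:
        _stage("cgi")
        table = cg.cgi_methylation_table(sample_calls, genome.cgis, genome,
                                         dmr_params)
        table.to_csv(out / "cgi_table.tsv", sep="\t", index=False)
        bundle["cgi_table"] = table
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cgi", e) from e

    if {"oocyte", "sperm"} <= set(config.samples):
        try:
            _stage("gdmr")
            sets = cg.classify_cgi_sets(table, dmr_params)
            gdmr = sets["gdmr"].copy()
            if len(gdmr):
                gdmr["location"] = cg.classify_gdmr_location(
                    gdmr, genome.genes, dmr_params.promoter_upstream)
                if "blastocyst" in table.columns:
                    gdmr = cg.classify_postfertilization_fate(
                        gdmr, params=dmr_params)
            gdmr.to_csv(out / "gdmr.tsv", sep="\t", index=False)
            bundle["gdmr_sets"] = sets
            bundle["gdmr"] = gdmr
            loglines.append(
                f"gdmr: thresholds hi={dmr_params.hi} lo={dmr_params.lo} "
                f"resist_min={dmr_params.resist_min}; "
                f"n_oocyte={len(sets['oocyte_gdmr'])} "
                f"n_sperm={len(sets['sperm_gdmr'])}")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("gdmr", e) from e
    else:
        loglines.append("gdmr: skipped (needs both oocyte and sperm samples)")

    if len(genome.icrs):
        try:
            _stage("icr")
            icr = cg.region_methylation(sample_calls, genome.icrs)
            icr.to_csv(out / "icr_table.tsv", sep="\t", index=False)
            bundle["icr_table"] = icr
        except Exception as e:  # noqa: BLE001
            raise PipelineError("icr", e) from e

    try:
        _stage("expression")
        tags = sim.simulate_mrna_tags(
            genome, n_tags=config.n_tags,
            seed=stage_seed(config.seed, "tags"))
        write_fastq(tags, out / "mrna_tags.fastq")
        records = ex.assign_expression_groups(ex.compute_rpkm(tags, genome))
        records.to_csv(out / "expression.tsv", sep="\t", index=False)
        bundle["expression"] = records
        if "oocyte" in sample_calls:
            calls = sample_calls["oocyte"]
            prof = pd.concat([
                ex.metagene_methylation_profile(calls, genome, records, a)
                for a in ("TSS", "TTS")])
            prof.to_csv(out / "metagene.tsv", sep="\t", index=False)
            bundle["metagene"] = prof
            if len(records) >= 10:
                corr = {r: ex.expression_methylation_correlation(
                    records, calls, genome, r)
                    for r in ("promoter", "gene_body_1", "gene_body_2")}
                bundle["correlations"] = corr
                loglines.append("correlations: " + "; ".join(
                    f"{r}: rho={c.spearman_rho:.3f} p={c.p_value:.2e}"
                    for r, c in corr.items()))
            else:
                loglines.append("correlations: skipped (fewer than 10 genes)")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("expression", e) from e

    _stage("manifest")
    logpath.write_text("\n".join(loglines) + "\n")
    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {"seed": config.seed,
                "config": dataclasses.asdict(config),
                "files": {str(p.relative_to(out)): _sha256(p) for p in files}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    bundle["outdir"] = out
    return bundle
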