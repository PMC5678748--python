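"""End-to-end runs from a configuration file, emitting tidy summary tables.

A :class:`RunConfig` names the inputs (genome FASTA, transcript table,
mutation calls, hexamer list, covariate tables) and the analysis
parameters, every one of which defaults to the study's standard value
(20 bp flanks, 40 bp core, 160 bp minimum exon, 69 bp ESE end window,
distance-2 non-ESE filter, B = 500 bootstrap replicates). Cohorts are
processed independently and combined by Fisher's method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .depletion import ese_study, flank_core_study
from .hexamers import read_hexamer_list
from .intervals import parse_transcript_table, select_internal_coding_exons
from .mutations import read_mutations, records_to_frame
from .strata import (
    exons_for_genes,
    exons_for_keys,
    partition_genes,
    quartile_strata,
    run_stratified_comparison,
    split_samples,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str = ""
    transcripts: str = ""
    transcript_dialect: str = "genepred"
    mutations: str = ""
    mutation_dialect: str = "maf"
    column_map: dict = field(default_factory=dict)
    ese_hexamers: str = ""
    exon_scores: str = ""
    gene_classes: str = ""
    sample_table: str = ""
    out_dir: str = "results"
    # parameters (defaults = study values)
    flank_len: int = 20
    core_len: int = 40
    min_exon: int = 160
    end_exclusion: int = 0
    ese_end_window: int = 69
    non_ese_min_distance: int = 2
    cpg_mask: bool = False
    consequence: str = "synonymous"
    B: int = 500
    confidence: float = 0.95
    seed: int = 0
    cohorts: dict = field(default_factory=dict)  # cohort -> [sample ids]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _load_inputs(config: RunConfig):
    genome = Fasta(config.genome, as_raw=False, sequence_always_upper=True)
    transcripts = parse_transcript_table(config.transcripts, config.transcript_dialect)
    exons = select_internal_coding_exons(transcripts, min_length=config.min_exon)
    records = read_mutations(
        config.mutations,
        dialect=config.mutation_dialect,
        column_map=config.column_map or None,
    )
    muts = records_to_frame(records)
    cohorts = config.cohorts or {
        "all": sorted(muts["sample_id"].unique().tolist())
    }
    return genome, transcripts, exons, muts, cohorts


def _study_tables(result, prefix: str, out_dir: Path) -> dict:
    paths = {}
    cohort_table = result.cohort_table()
    g1, g2 = result.groups
    combined_row = pd.DataFrame(
        [{
            "comparison": f"{g1}_vs_{g2}",
            "method": "fisher",
            "chi2": result.combined.chi2_stat,
            "df": result.combined.df,
            "combined_p": result.combined.combined_p,
            "cohens_d": result.combined.cohens_d,
            "d_ci_low": result.combined.d_ci[0],
            "d_ci_high": result.combined.d_ci[1],
            "depletion": result.combined.depletion,
        }]
    )
    for name, frame in (
        ("cohorts", cohort_table),
        ("combined", combined_row),
        ("per_tumour", result.per_tumour),
    ):
        path = out_dir / f"{prefix}_{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    return paths


def run_flank_core(config: RunConfig) -> dict:
    """Flank-vs-core analysis from a config; writes summary TSVs."""
    genome, _transcripts, exons, muts, cohorts = _load_inputs(config)
    n_syn = int((muts["consequence"] == "synonymous").sum())
    if config.consequence == "synonymous" and n_syn == 0:
        raise ValueError(
            f"no synonymous mutations after filtering ({len(muts)} records read)"
        )
    result = flank_core_study(
        muts, exons, genome, cohorts,
        flank_len=config.flank_len, core_len=config.core_len,
        end_exclusion=config.end_exclusion, cpg_mask=config.cpg_mask,
        consequence=config.consequence, B=config.B,
        confidence=config.confidence, seed=config.seed,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _study_tables(result, "flank_core", out_dir)
    report(config, {"analysis": "flank_core", "tables": paths,
                    "n_records": len(muts), "n_synonymous": n_syn})
    return {"result": result, "tables": paths}


def run_ese(config: RunConfig) -> dict:
    """ESE-vs-non-ESE analysis from a config; writes summary TSVs."""
    genome, _transcripts, exons, muts, cohorts = _load_inputs(config)
    ese = read_hexamer_list(config.ese_hexamers, provenance="ese")
    result = ese_study(
        muts, exons, genome, ese, cohorts,
        end_window=config.ese_end_window,
        min_distance=config.non_ese_min_distance,
        cpg_mask=config.cpg_mask, consequence=config.consequence,
        B=config.B, confidence=config.confidence, seed=config.seed,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _study_tables(result, "ese", out_dir)
    report(config, {"analysis": "ese", "tables": paths, "n_records": len(muts)})
    return {"result": result, "tables": paths}


def run_strata(config: RunConfig) -> dict:
    """Covariate-stratified flank/core comparisons from a config."""
    genome, transcripts, exons, muts, cohorts = _load_inputs(config)
    samples = sorted({s for lst in cohorts.values() for s in lst})
    strata = {}
    if config.exon_scores:
        scores = pd.read_csv(config.exon_scores, sep="\t").set_index("exon")
        for score_name in ("nucleosome", "replication_timing"):
            if score_name in scores.columns:
                high, low = quartile_strata(scores[score_name])
                strata[f"{score_name}_high"] = {"exons": exons_for_keys(exons, high)}
                strata[f"{score_name}_low"] = {"exons": exons_for_keys(exons, low)}
    if config.gene_classes:
        table = pd.read_csv(config.gene_classes, sep="\t")
        gene_ids = {t.gene_id for t in transcripts}
        for label, genes in partition_genes(table, gene_ids).items():
            strata[label] = {"exons": exons_for_genes(exons, genes)}
        if "essentiality" in table.columns:
            for label in ("essential", "non_essential"):
                genes = set(table.loc[table["essentiality"] == label, "gene_id"])
                strata[label] = {"exons": exons_for_genes(exons, genes)}
    if config.sample_table:
        table = pd.read_csv(config.sample_table, sep="\t")
        for label, ids in split_samples(table).items():
            strata[f"msi_{label}"] = {"samples": ids & set(samples)}
    if not strata:
        raise ValueError("no covariate inputs supplied; nothing to stratify")
    table = run_stratified_comparison(
        strata, muts, genome, exons, samples,
        flank_len=config.flank_len, core_len=config.core_len,
        end_exclusion=config.end_exclusion, cpg_mask=config.cpg_mask,
        consequence=config.consequence, B=config.B,
        confidence=config.confidence, seed=config.seed,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "strata_summary.tsv"
    table.to_csv(path, sep="\t", index=False)
    report(config, {"analysis": "strata", "tables": {"strata": str(path)}})
    return {"table": table, "path": str(path)}


def report(config: RunConfig, payload: dict) -> None:
    """Append a machine-readable run-log entry (idempotent per analysis)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.json"
    entries = {}
    if log_path.exists():
        entries = json.loads(log_path.read_text())
    payload = dict(payload)
    payload["seed"] = config.seed
    payload["version"] = __version__
    payload["parameters"] = {
        k: getattr(config, k)
        for k in ("flank_len", "core_len", "min_exon", "end_exclusion",
                  "ese_end_window", "non_ese_min_distance", "cpg_mask", "B",
                  "confidence")
    }
    entries[payload["analysis"]] = payload
    log_path.write_text(json.dumps(entries, indent=2, sort_keys=True))
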