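"""End-to-end pipeline orchestration and cohort bookkeeping.

Stage order: preprocess (QC, optional gene-id aggregation, size-factor
normalization, CNR against tissue-matched controls) -> pathway activation
scoring -> marker stratification and correlation screens -> differential
genes/pathways -> transposable-element comparison.  Every output table
carries a provenance header (tool version, config hash, seed) and
``summary.json`` aggregates the counts downstream reporting consumes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as tio
from . import preprocess as pp
from .differential import DiffConfig, differential_genes, differential_pal, group_report
from .errors import ConfigError, StageError
from .pal import pal_matrix
from .retro import aggregate_subfamilies, te_group_compare
from .screen import (
    ScreenConfig,
    annotate_tf,
    classify_tert,
    cohort_summary,
    correlation_screen,
    tf_counts,
)

logger = logging.getLogger("tertscape")

SUMMARY_REQUIRED_KEYS = (
    "provenance",
    "n_samples_input",
    "n_samples_qc",
    "cohort",
    "gene_screen",
    "pal_screen",
    "differential",
    "mutation_bookkeeping",
)


@dataclass
class RunConfig:
    """Paths and thresholds of a full pipeline run."""

    counts: str
    samples: str
    pathways: str
    out_dir: str
    gene_map: str | None = None
    te_counts: str | None = None
    tf_list: str | None = None
    min_reads: int = 3_500_000
    pseudocount: float = 1.0
    min_coverage: int = 1
    marker: str = "TERT"
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def mutation_bookkeeping(samples: pd.DataFrame) -> dict[str, int]:
    """Promoter-mutation assay counts, overall and among expressing samples.

    ``n_assayed`` counts samples with a known mutation status; ``n_mut``
    counts any of C228T/A, C250T/A.  Restricted to marker-positive samples,
    ``pct_mut_expressing`` is 100 * n_mut_expressing / (n_wt_expressing +
    n_mut_expressing) rounded to the nearest integer.
    """
    status = samples["mutation_status"]
    assayed = samples[status != "unknown"]
    is_mut = assayed["mutation_status"] != "wt"
    expressing = assayed[assayed["tert_stratum"] == "pos"]
    n_wt_expr = int((expressing["mutation_status"] == "wt").sum())
    n_mut_expr = int((expressing["mutation_status"] != "wt").sum())
    denom = n_wt_expr + n_mut_expr
    return {
        "n_assayed": int(len(assayed)),
        "n_wt": int((~is_mut).sum()),
        "n_mut": int(is_mut.sum()),
        "n_wt_expressing": n_wt_expr,
        "n_mut_expressing": n_mut_expr,
        "pct_mut_expressing": int(round(100.0 * n_mut_expr / denom)) if denom else 0,
    }


def validate_summary(summary: dict) -> None:
    """Light structural check of summary.json content."""
    missing = [k for k in SUMMARY_REQUIRED_KEYS if k not in summary]
    if missing:
        raise ConfigError(f"summary missing key(s): {missing}")
    for key in ("n_samples_input", "n_samples_qc"):
        if not isinstance(summary[key], int):
            raise ConfigError(f"summary[{key!r}] must be an integer")
    for key in ("provenance", "cohort", "gene_screen", "pal_screen",
                "differential", "mutation_bookkeeping"):
        if not isinstance(summary[key], dict):
            raise ConfigError(f"summary[{key!r}] must be an object")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage on the configured inputs; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"tertscape v{__version__} | config_hash={cfg.config_hash()} | seed={cfg.seed}"
    provenance = {"version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}

    def _stage(name: str):
        logger.info("stage: %s", name)
        return name

    # ---- preprocess ------------------------------------------------------
    stage = _stage("preprocess")
    try:
        counts = tio.read_counts_tsv(cfg.counts)
        samples = tio.read_sample_table(cfg.samples)
        n_input = counts.shape[1]
        counts, qc_report = pp.qc_filter_samples(counts, cfg.min_reads)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t")
        if counts.shape[1] == 0:
            raise StageError(stage, "no sample passed QC")
        if cfg.gene_map:
            counts = pp.aggregate_gene_ids(counts, tio.read_gene_id_map(cfg.gene_map))
        samples = samples.loc[[s for s in samples.index if s in counts.columns]]
        sf = pp.size_factors(counts, fallback=True)
        norm = pp.normalize(counts, sf)
        cnr = pp.cnr(norm, samples, pseudocount=cfg.pseudocount)
        tio.write_matrix_tsv(norm, out / "normalized.tsv", prov)
        tio.write_matrix_tsv(cnr, out / "cnr.tsv", prov)
        logger.info("%d/%d samples retained; %d genes", counts.shape[1], n_input, counts.shape[0])
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- pathway activation ---------------------------------------------
    stage = _stage("pal")
    try:
        library = tio.read_signed_gmt(cfg.pathways)
        pal, coverage = pal_matrix(cnr, library, min_coverage=cfg.min_coverage)
        tio.write_matrix_tsv(pal, out / "pal.tsv", prov)
        tio.write_matrix_tsv(coverage, out / "pal_coverage.tsv", prov)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stratify & screen ----------------------------------------------
    stage = _stage("screen")
    try:
        strata = classify_tert(counts, marker=cfg.marker)
        samples = samples.copy()
        tumor_ids = samples.index[samples["role"] == "tumor"]
        samples.loc[tumor_ids, "tert_stratum"] = strata.reindex(tumor_ids)
        summary_table = cohort_summary(samples)
        summary_table.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

        target = norm.loc[cfg.marker, list(tumor_ids)]
        gene_features = norm.loc[norm.index != cfg.marker, list(tumor_ids)]
        gene_screen = correlation_screen(target, gene_features, cfg.screen)
        if cfg.tf_list:
            gene_screen = annotate_tf(gene_screen, tio.read_gene_list(cfg.tf_list))
        pal_screen = correlation_screen(target, pal[list(tumor_ids)], cfg.screen)
        gene_screen.to_csv(out / "gene_screen.tsv", sep="\t")
        pal_screen.to_csv(out / "pal_screen.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- differential ----------------------------------------------------
    stage = _stage("diff")
    try:
        ref_label = cfg.diff.reference_group
        alt_label = "pos" if ref_label == "neg" else "neg"
        ref_ids = [s for s in tumor_ids if samples.loc[s, "tert_stratum"] == ref_label]
        alt_ids = [s for s in tumor_ids if samples.loc[s, "tert_stratum"] == alt_label]
        diff_genes = differential_genes(norm, ref_ids, alt_ids, cfg.diff)
        diff_pal, untestable = differential_pal(pal, ref_ids, alt_ids, cfg.diff)
        diff_genes.to_csv(out / "diff_genes.tsv", sep="\t")
        diff_pal.to_csv(out / "diff_pal.tsv", sep="\t")
        report = group_report(diff_genes, diff_pal)
        report["pathways_untestable"] = len(untestable)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- transposable elements ------------------------------------------
    te_summary: dict = {}
    if cfg.te_counts:
        stage = _stage("te")
        try:
            te_raw, subfamily = tio.read_te_counts(cfg.te_counts)
            te_raw = te_raw[[c for c in te_raw.columns if c in counts.columns]]
            sub, _ = aggregate_subfamilies(te_raw, subfamily)
            te_diff = te_group_compare(sub, counts[list(tumor_ids)], ref_ids, alt_ids, cfg.diff)
            te_diff.to_csv(out / "te_diff.tsv", sep="\t")
            te_summary = {
                "n_subfamilies": int(len(te_diff)),
                "n_significant": int(te_diff["significant"].sum()),
            }
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- summary ---------------------------------------------------------
    total_row = summary_table.iloc[-1]
    passing = gene_screen[gene_screen["passes"]]
    pal_passing = pal_screen[pal_screen["passes"]]
    summary = {
        "provenance": provenance,
        "n_samples_input": int(n_input),
        "n_samples_qc": int(counts.shape[1]),
        "cohort": {
            "n_pos": int(total_row["n_pos"]),
            "n_neg": int(total_row["n_neg"]),
            "pct_pos": float(total_row["pct_pos"]),
        },
        "gene_screen": {
            "n_pass": int(len(passing)),
            "n_pos": int((passing["direction"] == "pos").sum()),
            "n_neg": int((passing["direction"] == "neg").sum()),
            **(tf_counts(gene_screen) if "is_tf" in gene_screen.columns else {}),
        },
        "pal_screen": {
            "n_pass": int(len(pal_passing)),
            "n_pos": int((pal_passing["direction"] == "pos").sum()),
            "n_neg": int((pal_passing["direction"] == "neg").sum()),
        },
        "differential": report,
        "mutation_bookkeeping": mutation_bookkeeping(samples),
        "te": te_summary,
    }
    validate_summary(summary)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return out
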