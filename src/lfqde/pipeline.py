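"""End-to-end orchestration of the analysis stages.

A pipeline run reads a protein-group table, design and transcript summary,
preprocesses the intensities, tests each configured contrast, compares the
primary contrast with the transcript table, optionally runs enrichment, and
writes every result as a TSV plus a run manifest.  Stages never mutate each
other's outputs, so reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, concordance, de, enrichment, ingest, preprocess

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "alpha": 0.05,
    "min_bio": 2,
    "intensity_regex": r"^Intensity (.+)$",
    "enrichment": None,   # optional: {"gmt": path, "mode": "ora"|"gsea", ...}
    "seed": 0,
}


def validate_config(config: dict) -> dict:
    cfg = {**DEFAULTS, **config}
    for key in ("protein_groups", "design", "out_dir"):
        if key not in cfg:
            raise ConfigError(f"config missing required key {key!r}")
    if "contrasts" not in cfg or not cfg["contrasts"]:
        raise ConfigError("config must list at least one contrast")
    for c in cfg["contrasts"]:
        if not {"a", "b", "paired"} <= set(c):
            raise ConfigError(f"contrast entry needs a, b, paired: {c}")
    return cfg


def run_pipeline(config: dict) -> Path:
    """Execute the full pipeline and return the result directory."""
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    col_cfg = ingest.ColumnConfig(intensity_regex=cfg["intensity_regex"])
    table = ingest.read_protein_groups(cfg["protein_groups"], col_cfg)
    design = ingest.read_design(cfg["design"])
    ingest.check_runs_in_design(table, design)
    conditions = set(design["condition"])
    for c in cfg["contrasts"]:
        for side in ("a", "b"):
            if c[side] not in conditions:
                raise ConfigError(
                    f"contrast condition {c[side]!r} absent from design")

    stages = []
    table = ingest.apply_row_filters(table)
    stages.append("ingest")

    matrix = preprocess.preprocess(table, design)
    matrix.values.to_csv(out_dir / "normalized_matrix.tsv", sep="\t")
    matrix.detected.to_csv(out_dir / "detection_mask.tsv", sep="\t")
    qc = []
    for cond in matrix.conditions():
        if len(matrix.samples_for(cond)) >= 2:
            rc = preprocess.replicate_correlation(matrix, cond)
            rc.insert(0, "condition", cond)
            qc.append(rc)
    if qc:
        pd.concat(qc, ignore_index=True).to_csv(
            out_dir / "qc_replicate_correlation.tsv", sep="\t", index=False)
    stages.append("preprocess")

    de_tables = {}
    for c in cfg["contrasts"]:
        result = de.run_contrast(matrix, (c["a"], c["b"]), paired=c["paired"],
                                 alpha=cfg["alpha"], min_bio=cfg["min_bio"])
        name = f"de_{c['a']}_vs_{c['b']}"
        de.write_de_table(result, out_dir / f"{name}.tsv")
        de_tables[(c["a"], c["b"])] = result
    stages.append("de")

    if cfg.get("transcripts"):
        rna = ingest.read_transcript_table(cfg["transcripts"])
        first = cfg["contrasts"][0]
        de_table = de_tables[(first["a"], first["b"])]
        id_map = table.gene_ids.dropna()
        matched = concordance.match_and_restrict(de_table, rna, id_map)
        classified = concordance.classify_concordance(
            matched, alpha_prot=cfg["alpha"], alpha_rna=cfg["alpha"])
        classified.to_csv(out_dir / "concordance.tsv", sep="\t")
        stages.append("concordance")

    enr = cfg.get("enrichment")
    if enr:
        sets = ingest.read_gene_sets(enr["gmt"])
        first = cfg["contrasts"][0]
        de_table = de_tables[(first["a"], first["b"])]
        if enr.get("mode", "ora") == "ora":
            background = set(de_table.index[de_table["status"] == "tested"])
            query = set(de_table.index[de_table["de"].fillna(False)])
            result = enrichment.hypergeom_enrich(query, background, sets,
                                                 min_size=enr.get("min_size", 10),
                                                 max_size=enr.get("max_size", 500))
        else:
            ranked = enrichment.rank_statistic(de_table)
            result = enrichment.gsea_permutation(
                ranked, sets, n_perm=enr.get("n_perm", 1000),
                seed=cfg["seed"], min_size=enr.get("min_size", 10),
                max_size=enr.get("max_size", 500))
        result.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        stages.append("enrichment")

    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "stages": stages,
        "parameters": {k: v for k, v in cfg.items()
                       if k not in ("protein_groups", "design", "transcripts",
                                    "out_dir")},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out_dir
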