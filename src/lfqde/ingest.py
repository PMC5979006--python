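"""Readers, writers and row filters for the pipeline's tabular inputs.

The protein-group reader follows the MaxQuant ``proteinGroups.txt`` dialect:
one row per protein group, per-run intensity columns matched by a
configurable regular expression, and the three QC flag columns
("Only identified by site", "Reverse", "Potential contaminant") marked
with ``+``.  Zeros and empty cells both denote nondetection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FLAG_COLUMNS = ("only_by_site", "reverse", "contaminant")

#: default MaxQuant column names for the three QC flags
MAXQUANT_FLAG_NAMES = {
    "only_by_site": "Only identified by site",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}


class IngestError(ValueError):
    """Fatal problem in an input table."""


@dataclass
class ColumnConfig:
    """Column-name mapping for a protein-group table.

    ``intensity_regex`` must contain one capture group giving the run label;
    the default matches plain MaxQuant ``Intensity <run>`` columns.  Use
    ``^LFQ intensity (.+)$`` for LFQ-normalized intensities.
    """

    protein_id: str = "Protein IDs"
    gene_id: str | None = "Gene names"
    intensity_regex: str = r"^Intensity (.+)$"
    flag_names: dict = field(default_factory=lambda: dict(MAXQUANT_FLAG_NAMES))


@dataclass
class RunIntensityTable:
    """Raw per-run protein intensities plus QC flags.

    ``intensities`` is a proteins x runs frame (index = protein id, columns =
    run labels), nonnegative, with 0 meaning nondetected.  ``flags`` is a
    boolean frame with columns ``only_by_site``, ``reverse``,
    ``contaminant``; ``gene_ids`` maps protein id -> gene id (may be empty).
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    gene_ids: pd.Series

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise IngestError("intensity table contains non-finite values")
        if (vals < 0).any():
            raise IngestError("intensity table contains negative values")
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise IngestError(f"duplicate protein id: {dup!r}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def run_labels(self) -> list[str]:
        return list(self.intensities.columns)


def read_protein_groups(path: str | Path,
                        config: ColumnConfig | None = None) -> RunIntensityTable:
    """Read a tab-separated protein-group table.

    Empty cells, ``NaN`` strings and 0 all map to nondetected (0); flag
    columns absent from the file are treated as all-false with a warning.
    """
    config = config or ColumnConfig()
    path = Path(path)
    if not path.exists():
        raise IngestError(f"protein-group file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if config.protein_id not in df.columns:
        raise IngestError(f"missing mandatory column {config.protein_id!r}")
    pattern = re.compile(config.intensity_regex)
    run_cols: dict[str, str] = {}
    for col in df.columns:
        m = pattern.match(col)
        if m:
            run_cols[col] = m.group(1)
    if not run_cols:
        raise IngestError(
            f"no intensity column matches regex {config.intensity_regex!r}")

    inten = pd.DataFrame(index=df[config.protein_id].to_numpy())
    for col, run in run_cols.items():
        raw = df[col].str.strip()
        raw = raw.replace({"": "0", "NaN": "0", "nan": "0", "NA": "0"})
        try:
            inten[run] = raw.astype(float).to_numpy()
        except ValueError:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna()]
            row = bad.index[0]
            raise IngestError(
                f"non-numeric intensity in column {col!r}, row {row}: "
                f"{bad.iloc[0]!r}") from None
    inten = inten.fillna(0.0)

    flags = pd.DataFrame(False, index=inten.index, columns=list(FLAG_COLUMNS))
    for key in FLAG_COLUMNS:
        name = config.flag_names.get(key)
        if name is not None and name in df.columns:
            flags[key] = (df[name].str.strip() == "+").to_numpy()
        else:
            log.warning("flag column %r absent; treating as all-false", name)

    if config.gene_id is not None and config.gene_id in df.columns:
        gene_ids = pd.Series(df[config.gene_id].to_numpy(), index=inten.index)
        gene_ids = gene_ids.replace("", np.nan)
    else:
        gene_ids = pd.Series(np.nan, index=inten.index, dtype=object)

    return RunIntensityTable(intensities=inten, flags=flags, gene_ids=gene_ids)


def write_protein_groups(table: RunIntensityTable, path: str | Path,
                         config: ColumnConfig | None = None) -> None:
    """Write a table in the same dialect :func:`read_protein_groups` reads."""
    config = config or ColumnConfig()
    regex = config.intensity_regex
    # invert the capture-group regex into a format template, e.g.
    # "^Intensity (.+)$" -> "Intensity {}"
    template = regex.lstrip("^").rstrip("$").replace("(.+)", "{}")
    out = pd.DataFrame({config.protein_id: table.intensities.index})
    if config.gene_id is not None:
        out[config.gene_id] = table.gene_ids.fillna("").to_numpy()
    for run in table.intensities.columns:
        col = table.intensities[run]
        out[template.format(run)] = [
            "" if v == 0 else repr(float(v)) for v in col]
    for key in FLAG_COLUMNS:
        name = config.flag_names.get(key)
        if name:
            out[name] = np.where(table.flags[key].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)


def apply_row_filters(table: RunIntensityTable) -> RunIntensityTable:
    """Drop protein groups flagged only-by-site, reverse or contaminant."""
    bad = table.flags.any(axis=1)
    for key in FLAG_COLUMNS:
        n = int(table.flags[key].sum())
        if n:
            log.info("row filter: removing %d proteins flagged %s", n, key)
    keep = ~bad.to_numpy()
    return RunIntensityTable(
        intensities=table.intensities.loc[keep],
        flags=table.flags.loc[keep],
        gene_ids=table.gene_ids.loc[keep],
    )


# ---------------------------------------------------------------------------
# sample design


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a run design table (columns run, condition, culture, tech_rep)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"run", "condition", "culture", "tech_rep"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"design table missing columns: {sorted(missing)}")
    df["tech_rep"] = df["tech_rep"].astype(int)
    return validate_design(df)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    if design["run"].duplicated().any():
        raise IngestError("design table has duplicate run labels")
    return design


def check_runs_in_design(table: RunIntensityTable, design: pd.DataFrame) -> None:
    missing = set(table.run_labels) - set(design["run"])
    if missing:
        raise IngestError(f"runs absent from design: {sorted(missing)}")


# ---------------------------------------------------------------------------
# transcripts


def read_transcript_table(path: str | Path) -> pd.DataFrame:
    """Read a transcript DE summary (gene_id, log2fc, fdr, mean_expr[, detected])."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"transcript table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise IngestError("transcript table has duplicate gene ids")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise IngestError("transcript fdr outside [0, 1]")
    if "detected" not in df.columns:
        df["detected"] = True
    return df


def filter_low_expression_transcripts(counts: pd.DataFrame,
                                      min_cpm: float = 1.0,
                                      min_samples: int = 4) -> set[str]:
    """Return gene ids with cpm > ``min_cpm`` in at least ``min_samples`` samples.

    ``counts`` is genes x samples of nonnegative raw counts; cpm is computed
    per sample as count / column sum * 1e6, so the filter is invariant to
    per-sample library-size scaling.
    """
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = counts.columns[np.nonzero(totals <= 0)[0][0]]
        raise IngestError(f"sample {bad!r} has zero total count")
    cpm = counts.to_numpy(dtype=float) / totals * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return set(counts.index[keep])


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IngestError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise IngestError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise IngestError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
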