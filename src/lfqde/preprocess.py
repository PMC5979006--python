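"""Preprocessing chain for LFQ intensities.

The stages run in a fixed order mirroring how label-free data are usually
prepared for moderated-t testing: per-run minimum imputation of nondetected
values, median summarization of technical replicates into one column per
biological sample, log2 transform, and quantile normalization.  Detection
(any nonzero technical replicate) is recorded *before* imputation and
carried alongside the values, because the tiered tests downstream are
driven by the detection mask, not by imputed numbers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import RunIntensityTable

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class SampleMatrix:
    """Protein x biological-sample values with a detection mask.

    ``values`` and ``detected`` share the same index (protein ids) and
    columns (sample labels ``condition:culture``).  ``sample_info`` has one
    row per sample column with ``condition`` and ``culture``.  ``is_log``
    records whether values are on the log2 scale.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    sample_info: pd.DataFrame
    is_log: bool = False

    def samples_for(self, condition: str) -> list[str]:
        sel = self.sample_info[self.sample_info["condition"] == condition]
        return list(sel.index)

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_info["condition"]))


def detection_mask(table: RunIntensityTable) -> pd.DataFrame:
    """Boolean per-(protein, run) detection: intensity strictly positive."""
    return table.intensities > 0


def impute_run_minimum(table: RunIntensityTable) -> RunIntensityTable:
    """Replace zeros in each run by that run's minimum nonzero intensity.

    Detected values are never altered and never decreased.  A run with no
    detected protein at all cannot define a minimum and is a fatal error.
    """
    vals = table.intensities.to_numpy(dtype=float).copy()
    for j, run in enumerate(table.intensities.columns):
        col = vals[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise PreprocessError(f"run {run!r} has no detected intensity")
        col[col == 0] = nonzero.min()
    out = table.intensities.copy()
    out.loc[:, :] = vals
    return RunIntensityTable(intensities=out, flags=table.flags,
                             gene_ids=table.gene_ids)


def summarize_technical_replicates(table: RunIntensityTable,
                                   design: pd.DataFrame,
                                   detected_runs: pd.DataFrame) -> SampleMatrix:
    """Collapse technical replicates to one median column per biological sample.

    ``detected_runs`` is the pre-imputation detection mask; a biological
    sample counts as detected when at least one of its technical replicates
    was nonzero before imputation.
    """
    design = design.set_index("run") if "run" in design.columns else design
    missing = set(table.run_labels) - set(design.index)
    if missing:
        raise PreprocessError(f"runs without design entry: {sorted(missing)}")

    groups: dict[str, list[str]] = {}
    info_rows = {}
    for run in table.run_labels:
        cond = design.loc[run, "condition"]
        cult = design.loc[run, "culture"]
        label = f"{cond}:{cult}"
        groups.setdefault(label, []).append(run)
        info_rows[label] = {"condition": cond, "culture": cult}

    values = pd.DataFrame(index=table.protein_ids)
    detected = pd.DataFrame(index=table.protein_ids)
    for label, runs in groups.items():
        values[label] = table.intensities[runs].median(axis=1)
        detected[label] = detected_runs[runs].any(axis=1)
    sample_info = pd.DataFrame.from_dict(info_rows, orient="index")
    sample_info = sample_info.loc[values.columns]
    return SampleMatrix(values=values, detected=detected,
                        sample_info=sample_info, is_log=False)


def log_transform(matrix: SampleMatrix) -> SampleMatrix:
    """log2-transform all values (requires strictly positive entries)."""
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise PreprocessError(
            "nonpositive value in log transform; run imputation first")
    out = matrix.values.copy()
    out.loc[:, :] = np.log2(vals)
    return SampleMatrix(values=out, detected=matrix.detected,
                        sample_info=matrix.sample_info, is_log=True)


def quantile_normalize(matrix: SampleMatrix) -> SampleMatrix:
    """Quantile-normalize samples to the mean of their order statistics.

    Each sample's ordered values are replaced by the across-sample mean of
    order statistics; tied values receive the average (via average ranks and
    linear interpolation) of the reference values their ranks span, so the
    map is rank-preserving and deterministic.  After normalization every
    sample's sorted value vector is identical.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n, m = vals.shape
    if m == 1:
        log.warning("quantile normalization with a single sample is a no-op")
        return matrix
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    res = matrix.values.copy()
    res.loc[:, :] = out
    return SampleMatrix(values=res, detected=matrix.detected,
                        sample_info=matrix.sample_info, is_log=matrix.is_log)


def preprocess(table: RunIntensityTable, design: pd.DataFrame) -> SampleMatrix:
    """Full chain: impute -> median-summarize -> log2 -> quantile-normalize."""
    mask = detection_mask(table)
    imputed = impute_run_minimum(table)
    sm = summarize_technical_replicates(imputed, design, mask)
    sm = log_transform(sm)
    return quantile_normalize(sm)


# ---------------------------------------------------------------------------
# detection summary


def detection_summary(matrix: SampleMatrix, min_bio: int = 2) -> pd.DataFrame:
    """Count detected biological samples per (protein, condition).

    Returns a frame indexed by protein with a two-level column per
    condition: ``(condition, 'n_detected')`` and ``(condition, 'detected')``
    where a protein counts as detected in a condition when at least
    ``min_bio`` of its biological replicates were detected.
    """
    pieces = {}
    for cond in matrix.conditions():
        cols = matrix.samples_for(cond)
        n = matrix.detected[cols].sum(axis=1).astype(int)
        pieces[(cond, "n_detected")] = n
        pieces[(cond, "detected")] = n >= min_bio
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


# ---------------------------------------------------------------------------
# QC statistics


def replicate_correlation(matrix: SampleMatrix, condition: str) -> pd.DataFrame:
    """Pairwise Pearson r between biological replicates of one condition.

    Computed on log2 values.  A pair involving a zero-variance sample has an
    undefined correlation and is reported as NaN.
    """
    cols = matrix.samples_for(condition)
    if len(cols) < 2:
        raise PreprocessError(
            f"condition {condition!r} has fewer than 2 samples")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        x = matrix.values[a].to_numpy(dtype=float)
        y = matrix.values[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append({"sample_a": a, "sample_b": b, "pearson_r": r})
    return pd.DataFrame(rows)


def cumulative_abundance(matrix: SampleMatrix, condition: str) -> pd.DataFrame:
    """Ranked cumulative-abundance curve for one condition.

    Proteins are ranked by mean linear-scale intensity (descending); the
    curve gives the cumulative fraction of total intensity.  Returns a frame
    with columns ``protein_id``, ``mean_intensity``, ``cum_fraction``.
    """
    cols = matrix.samples_for(condition)
    if not cols:
        raise PreprocessError(f"no samples for condition {condition!r}")
    vals = matrix.values[cols].to_numpy(dtype=float)
    linear = np.exp2(vals) if matrix.is_log else vals
    mean = linear.mean(axis=1)
    order = np.argsort(-mean, kind="stable")
    cum = np.cumsum(mean[order]) / mean.sum()
    return pd.DataFrame({
        "protein_id": matrix.values.index[order],
        "mean_intensity": mean[order],
        "cum_fraction": cum,
    })


def abundance_quartile_counts(curve: pd.DataFrame) -> dict[str, int]:
    """Proteins needed to reach 25/50/75/100% of total intensity."""
    cum = curve["cum_fraction"].to_numpy()
    out = {}
    for q in (0.25, 0.50, 0.75, 1.00):
        out[f"{int(q * 100)}%"] = int(np.searchsorted(cum, q - 1e-12) + 1)
    return out
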