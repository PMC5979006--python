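"""Comparison of protein-level and transcript-level differential expression.

Matched protein/transcript pairs are classified into mutually exclusive
concordance classes by significance and fold-change direction on each side.
Only features with both a detected protein and a detected transcript enter
the comparison, so every percentage reported here uses the matched,
restricted denominator.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CLASSES = ("concordant_up", "concordant_down", "discordant",
           "protein_only", "rna_only", "neither")


class ConcordanceError(ValueError):
    pass


def match_and_restrict(de: pd.DataFrame, rna: pd.DataFrame,
                       id_map: pd.Series | None = None) -> pd.DataFrame:
    """Join a protein DE table with a transcript DE table.

    ``de`` is indexed by protein id (columns ``log2fc``, ``q``, ``status``);
    ``rna`` has columns ``gene_id``, ``log2fc``, ``fdr``, ``detected``.
    ``id_map`` maps protein id -> gene id (identity when omitted).  Proteins
    without a detected transcript and transcripts without a protein are
    dropped; the counts are logged.  A protein mapping to several genes uses
    the first mapping with a warning.
    """
    de = de.copy()
    de.index.name = "protein_id"
    if id_map is None:
        de["gene_id"] = de.index
    else:
        if id_map.index.duplicated().any():
            log.warning("id map has multi-gene proteins; using first mapping")
            id_map = id_map[~id_map.index.duplicated(keep="first")]
        de["gene_id"] = de.index.map(id_map)

    rna = rna[rna["detected"].astype(bool)]
    rna = rna.rename(columns={"log2fc": "rna_log2fc", "fdr": "rna_fdr"})
    merged = de.reset_index().merge(
        rna[["gene_id", "rna_log2fc", "rna_fdr"]], on="gene_id", how="inner")
    merged = merged.rename(columns={"log2fc": "protein_log2fc",
                                    "q": "protein_q"})
    n_prot_dropped = len(de) - merged["protein_id"].nunique()
    n_rna_dropped = len(rna) - merged["gene_id"].nunique()
    log.info("matching dropped %d proteins without transcripts and %d "
             "transcripts without proteins", n_prot_dropped, n_rna_dropped)
    return merged.set_index("protein_id")


def classify_concordance(matched: pd.DataFrame, alpha_prot: float = 0.05,
                         alpha_rna: float = 0.05) -> pd.DataFrame:
    """Assign each matched feature one of the five-way concordance classes.

    Selectively expressed proteins (status ``selective_in_*``) carry no q
    value but are treated as significant with the sign of their reported
    fold change, flagged in the ``selective`` column.
    """
    if not (0 < alpha_prot < 1 and 0 < alpha_rna < 1):
        raise ConcordanceError("significance thresholds must lie in (0, 1)")
    out = matched.copy()
    selective = out.get("status", pd.Series("", index=out.index)) \
        .astype(str).str.startswith("selective_in_")
    out["selective"] = selective
    prot_sig = (out["protein_q"] < alpha_prot) | selective
    rna_sig = out["rna_fdr"] < alpha_rna

    psign = np.sign(out["protein_log2fc"].to_numpy(dtype=float))
    rsign = np.sign(out["rna_log2fc"].to_numpy(dtype=float))
    zero_sig = (psign == 0) & prot_sig | (rsign == 0) & rna_sig
    if zero_sig.any():
        log.warning("%d significant features with zero fold change; "
                    "classified by the other member's sign",
                    int(zero_sig.sum()))
        psign = np.where((psign == 0) & prot_sig, rsign, psign)
        rsign = np.where((rsign == 0) & rna_sig, psign, rsign)

    cls = np.full(len(out), "neither", dtype=object)
    both = prot_sig & rna_sig
    cls[both & (psign > 0) & (rsign > 0)] = "concordant_up"
    cls[both & (psign < 0) & (rsign < 0)] = "concordant_down"
    cls[both & (psign * rsign < 0)] = "discordant"
    cls[prot_sig & ~rna_sig] = "protein_only"
    cls[~prot_sig & rna_sig] = "rna_only"
    out["class"] = cls
    return out


def class_counts(table: pd.DataFrame) -> pd.Series:
    counts = table["class"].value_counts()
    return counts.reindex(CLASSES, fill_value=0)


def foldchange_correlation(matched: pd.DataFrame,
                           classes: list[str] | None = None) -> float:
    """Pearson r between protein and transcript log2 fold changes.

    ``classes`` restricts to a subset of concordance classes (requires
    :func:`classify_concordance` to have run).
    """
    sub = matched if classes is None else matched[matched["class"].isin(classes)]
    if len(sub) < 3:
        raise ConcordanceError(
            f"need >= 3 features for a correlation, got {len(sub)}")
    x = sub["protein_log2fc"].to_numpy(dtype=float)
    y = sub["rna_log2fc"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConcordanceError("zero-variance fold changes; r undefined")
    return float(stats.pearsonr(x, y).statistic)


def venn_summary(named_sets: dict[str, set]) -> dict[str, int]:
    """Region counts of the 2- or 3-set Venn partition.

    Keys are '&'-joined sorted set names; each element is counted once, in
    the region of exactly the sets that contain it.
    """
    if not 2 <= len(named_sets) <= 3:
        raise ConcordanceError("venn summary supports 2 or 3 sets")
    names = sorted(named_sets)
    universe = set().union(*named_sets.values())
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set().union(*(named_sets[n] for n in names
                                    if n not in combo)) if r < len(names) else set()
            counts["&".join(combo)] = len(inside - outside)
    counts["total"] = len(universe)
    return counts


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Share of ``numerator`` in ``denominator`` as a percentage."""
    if denominator <= 0:
        raise ConcordanceError("percentage with nonpositive denominator")
    return round(100.0 * numerator / denominator, digits)
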