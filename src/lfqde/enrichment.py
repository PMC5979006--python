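"""Over-representation (hypergeometric) and ranked GSEA analyses.

The over-representation test asks whether a query list (e.g. DE proteins)
overlaps a gene set more than expected under sampling without replacement
from a background; the background is the set of all features detected in
the samples entering the comparison, and sets are intersected with the
background before sizing.

The ranked analysis scores each set with the weighted Kolmogorov-Smirnov
running-sum statistic over a list ranked by a signed significance score
(by default -log10(q) signed by the fold change).  Significance comes from
gene-label permutations: random same-size member sets drawn from the ranked
universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .ingest import GeneSetCollection

log = logging.getLogger(__name__)

Q_FLOOR = 1e-300


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# over-representation


def hypergeom_enrich(query: set[str], background: set[str],
                     sets: GeneSetCollection, min_size: int = 10,
                     max_size: int = 500) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each set against the query.

    Returns one row per retained set with k (overlap), K (set size within
    background), n (query size), N (background size), p and BH q.
    """
    if not background:
        raise EnrichmentError("empty background")
    extra = query - background
    if extra:
        raise EnrichmentError(
            f"query contains {len(extra)} ids outside the background")
    N, n = len(background), len(query)
    rows = []
    for name, members in sorted(sets.items()):
        in_bg = members & background
        K = len(in_bg)
        if not min_size <= K <= max_size:
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# ranked GSEA


def rank_statistic(de: pd.DataFrame, q_col: str = "q",
                   fc_col: str = "log2fc") -> pd.Series:
    """Signed significance score per feature, sorted descending.

    score = -log10(q) * sign(log2fc), with q floored at 1e-300.  Features
    without a q value are skipped with a warning.  Ties are broken by id so
    the ordering is deterministic.
    """
    has_q = de[q_col].notna()
    if (~has_q).any():
        log.warning("rank statistic skipping %d features without q",
                    int((~has_q).sum()))
    sub = de[has_q]
    q = np.maximum(sub[q_col].to_numpy(dtype=float), Q_FLOOR)
    score = -np.log10(q) * np.sign(sub[fc_col].to_numpy(dtype=float))
    s = pd.Series(score, index=sub.index)
    order = sorted(s.index, key=lambda i: (-s.loc[i], str(i)))
    return s.loc[order]


def gsea_es(ranked: pd.Series, members: set[str], weight: float = 1.0
            ) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score for one set over a ranked list.

    Hits increment the running sum by |score|^weight normalized over the
    set's members; misses decrement by 1/(N-K).  Returns (es, running sum,
    leading-edge member ids): the extremum of the running sum by absolute
    value, and the members at or before the extremum (positive es) or after
    it (negative es).
    """
    ids = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(ids, list(members))
    K = int(hit.sum())
    N = ids.size
    if K == 0:
        raise EnrichmentError("set has no member in the ranked list")
    if K == N:
        raise EnrichmentError("set spans the whole ranked list")
    w = np.abs(scores) ** weight
    hit_total = w[hit].sum()
    if hit_total == 0:  # every member score is zero: no evidence either way
        return 0.0, np.zeros(N), []
    steps = np.where(hit, w / hit_total, -1.0 / (N - K))
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [str(i) for i in ids[: i_ext + 1][hit[: i_ext + 1]]]
    else:
        leading = [str(i) for i in ids[i_ext + 1:][hit[i_ext + 1:]]]
    return es, running, leading


def gsea_permutation(ranked: pd.Series, sets: GeneSetCollection,
                     n_perm: int = 1000, seed: int | np.random.Generator = 0,
                     weight: float = 1.0, min_size: int = 10,
                     max_size: int = 500) -> pd.DataFrame:
    """Gene-label permutation GSEA over a collection of sets.

    The null draws ``n_perm`` random member sets of matching size from the
    ranked universe.  perm_p = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm);
    NES = ES / mean |ES_null| over nulls of the same sign; BH across sets.
    """
    if n_perm < 100:
        raise EnrichmentError("need at least 100 permutations")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    universe = list(ranked.index)
    rows = []
    for name, members in sorted(sets.items()):
        in_list = members & set(universe)
        K = len(in_list)
        if not min_size <= K <= max_size or K == len(universe):
            continue
        es, _, leading = gsea_es(ranked, in_list, weight=weight)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            draw = rng.choice(len(universe), size=K, replace=False)
            null_members = {universe[i] for i in draw}
            null_es[b] = gsea_es(ranked, null_members, weight=weight)[0]
        perm_p = (1 + int((np.abs(null_es) >= abs(es)).sum())) / (1 + n_perm)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 \
            else null_es
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        rows.append({"set": name, "K": K, "es": es, "nes": nes,
                     "perm_p": perm_p,
                     "leading_edge": ",".join(sorted(leading))})
    out = pd.DataFrame(rows, columns=["set", "K", "es", "nes", "perm_p",
                                      "leading_edge"])
    out["q"] = bh_adjust(out["perm_p"].to_numpy()) if len(out) else []
    return out
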