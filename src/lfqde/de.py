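"""Empirical-Bayes moderated t-tests with tiered handling of missing data.

Per-protein residual variances :math:`s_g^2` with :math:`d_g` degrees of
freedom are shrunk toward a prior scaled-inverse-chi-square distribution
with hyperparameters :math:`(d_0, s_0^2)` estimated by matching the moments
of :math:`\\log s_g^2`.  The moderated statistic

.. math:: \\tilde t_g = \\frac{\\mathrm{log_2FC}_g}{\\sqrt{\\tilde s_g^2 c}},
          \\qquad \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g}

follows a Student t with :math:`d_0 + d_g` degrees of freedom under the
null (standard normal when :math:`d_0 = \\infty`).  ``c`` is the variance
scale of the effect: :math:`1/n` for a paired one-sample comparison of
per-culture differences, :math:`1/n_A + 1/n_B` for the unpaired pooled
comparison.

Proteins are partitioned by detection: those detected in every biological
sample of the contrast form the *complete* tier, those with some missing
values but at least one detected value in each condition form the *partial*
tier.  The hyperparameter fit and the Benjamini-Hochberg adjustment are
applied separately within each tier, so incomplete-data variances never
inform the complete-data prior.  Proteins detected in only one condition
are reported as *selectively expressed* without a test; the rest are
*not testable*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import SampleMatrix, detection_summary

log = logging.getLogger(__name__)

STATUS_TESTED = "tested"
STATUS_NOT_TESTABLE = "not_testable"
TIER_COMPLETE = "complete"
TIER_PARTIAL = "partial"


class DEError(ValueError):
    pass


@dataclass
class EBHyperparams:
    """Prior degrees of freedom and prior variance for variance shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise DEError("d0 must be positive (may be inf)")
        if not (self.s0_sq > 0 and np.isfinite(self.s0_sq)):
            raise DEError("s0_sq must be positive and finite")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DEError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# hyperparameter fit (log-moment matching on scaled chi-square variances)


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_eb_hyperparams(s2: np.ndarray, df: np.ndarray) -> EBHyperparams:
    """Estimate (d0, s0_sq) from observed sample variances and their df.

    Under the model s_g^2 ~ s0^2 * chi^2_{d_g}/d_g scaled by a
    chi^2_{d0}-distributed precision, e_g = ln s_g^2 - psi(d_g/2) +
    ln(d_g/2) has mean ln s0^2 + psi(d0/2) - ln(d0/2) and excess variance
    psi'(d0/2) beyond psi'(d_g/2); moment matching on (mean, variance) of
    e_g yields the estimates.  Zero variances are floored at 1e-3 times the
    smallest positive variance before taking logs.
    """
    s2 = np.asarray(s2, dtype=float).copy()
    df = np.asarray(df, dtype=float)
    if s2.size != df.size:
        raise DEError("s2 and df must have equal length")
    if s2.size == 0:
        raise DEError("no variances to fit")
    if s2.size < 10:
        log.warning("fitting EB hyperparameters on only %d variances", s2.size)
    if (s2 == 0).any():
        positive = s2[s2 > 0]
        if positive.size == 0:
            raise DEError("all sample variances are zero")
        floor = positive.min() * 1e-3
        log.info("flooring %d zero variances at %.3g", int((s2 == 0).sum()), floor)
        s2[s2 == 0] = floor

    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    G = e.size
    if G > 1:
        target = np.mean((e - e_bar) ** 2 * G / (G - 1)
                         - special.polygamma(1, df / 2.0))
    else:
        target = 0.0
    if target <= 0:
        return EBHyperparams(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * _trigamma_inverse(float(target))
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t


def moderated_t(log2fc: np.ndarray, s2: np.ndarray, df: np.ndarray,
                c: np.ndarray, hyper: EBHyperparams
                ) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    ``c`` is the per-protein variance scale factor of the effect estimate
    (1/n paired; 1/nA + 1/nB unpaired).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.isinf(hyper.d0):
        s2_tilde = np.full_like(s2, hyper.s0_sq)
        t = log2fc / np.sqrt(s2_tilde * c)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_tilde = (hyper.d0 * hyper.s0_sq + df * s2) / (hyper.d0 + df)
        t = log2fc / np.sqrt(s2_tilde * c)
        p = 2.0 * stats.t.sf(np.abs(t), hyper.d0 + df)
    return t, p


# ---------------------------------------------------------------------------
# testability classification


def classify_testability(matrix: SampleMatrix, contrast: tuple[str, str],
                         paired: bool, min_bio: int = 2,
                         min_pairs: int = 2, min_samples: int = 3
                         ) -> pd.DataFrame:
    """Assign each protein a status and the usable sample/pair set.

    Statuses: ``tested`` (>= 1 detected value in each condition and enough
    usable units to yield a residual variance), ``selective_in_<A|B>``
    (condition-level detection in one condition, zero detected values in the
    other), else ``not_testable``.  In a paired design the usable set is the
    cultures whose members are detected in *both* conditions.
    """
    cond_a, cond_b = contrast
    conds = set(matrix.sample_info["condition"])
    for cond in contrast:
        if cond not in conds:
            raise DEError(f"unknown condition {cond!r}")
    cols_a = matrix.samples_for(cond_a)
    cols_b = matrix.samples_for(cond_b)
    det = detection_summary(matrix, min_bio=min_bio)
    det_a = matrix.detected[cols_a]
    det_b = matrix.detected[cols_b]
    n_a = det_a.sum(axis=1)
    n_b = det_b.sum(axis=1)

    if paired:
        cult_a = {matrix.sample_info.loc[c, "culture"]: c for c in cols_a}
        cult_b = {matrix.sample_info.loc[c, "culture"]: c for c in cols_b}
        shared = sorted(set(cult_a) & set(cult_b))
        if len(shared) < 2:
            raise DEError("paired contrast needs >= 2 shared cultures")

    rows = []
    for pid in matrix.values.index:
        na, nb = int(n_a.loc[pid]), int(n_b.loc[pid])
        complete = (na == len(cols_a)) and (nb == len(cols_b))
        if na > 0 and nb > 0:
            if paired:
                usable = [cult for cult in shared
                          if matrix.detected.loc[pid, cult_a[cult]]
                          and matrix.detected.loc[pid, cult_b[cult]]]
                enough = len(usable) >= min_pairs
            else:
                usable = ([c for c in cols_a if matrix.detected.loc[pid, c]]
                          + [c for c in cols_b if matrix.detected.loc[pid, c]])
                enough = len(usable) >= min_samples
            if enough:
                rows.append((pid, STATUS_TESTED,
                             TIER_COMPLETE if complete else TIER_PARTIAL,
                             usable))
                continue
            rows.append((pid, STATUS_NOT_TESTABLE, None, usable))
            continue
        if nb == 0 and det.loc[pid, (cond_a, "detected")]:
            rows.append((pid, f"selective_in_{cond_a}", None, []))
        elif na == 0 and det.loc[pid, (cond_b, "detected")]:
            rows.append((pid, f"selective_in_{cond_b}", None, []))
        else:
            rows.append((pid, STATUS_NOT_TESTABLE, None, []))
    out = pd.DataFrame(rows, columns=["protein_id", "status", "tier", "usable"])
    return out.set_index("protein_id")


# ---------------------------------------------------------------------------
# effect and residual variance


def effect_and_variance(matrix: SampleMatrix, protein_id: str,
                        contrast: tuple[str, str], paired: bool,
                        usable: list[str]) -> tuple[float, float, int, float]:
    """(log2fc, s_g^2, d_g, c) for one protein over its usable units.

    Paired: one-sample statistics of the per-culture differences A_i - B_i
    (n-1 df, c = 1/n).  Unpaired: difference of group means with pooled
    variance (nA + nB - 2 df, c = 1/nA + 1/nB).
    """
    cond_a, cond_b = contrast
    if paired:
        diffs = np.array([
            matrix.values.loc[protein_id, f"{cond_a}:{cult}"]
            - matrix.values.loc[protein_id, f"{cond_b}:{cult}"]
            for cult in usable])
        n = diffs.size
        if n < 2:
            raise DEError("paired effect needs >= 2 pairs")
        return (float(diffs.mean()), float(diffs.var(ddof=1)), n - 1, 1.0 / n)
    vals_a = np.array([matrix.values.loc[protein_id, c] for c in usable
                       if matrix.sample_info.loc[c, "condition"] == cond_a])
    vals_b = np.array([matrix.values.loc[protein_id, c] for c in usable
                       if matrix.sample_info.loc[c, "condition"] == cond_b])
    na, nb = vals_a.size, vals_b.size
    dg = na + nb - 2
    if na < 1 or nb < 1 or dg < 1:
        raise DEError("unpaired effect needs both groups and >= 3 samples")
    ss = (vals_a.var(ddof=1) * (na - 1) if na > 1 else 0.0) \
        + (vals_b.var(ddof=1) * (nb - 1) if nb > 1 else 0.0)
    pooled = ss / dg
    return (float(vals_a.mean() - vals_b.mean()), float(pooled), dg,
            1.0 / na + 1.0 / nb)


# ---------------------------------------------------------------------------
# full contrast


def run_contrast(matrix: SampleMatrix, contrast: tuple[str, str],
                 paired: bool, alpha: float = 0.05, min_bio: int = 2,
                 min_pairs: int = 2, min_samples: int = 3) -> pd.DataFrame:
    """Run one two-condition comparison and return a DE result table.

    Columns: contrast, status, tier, log2fc, sg_sq, dg, t_mod, p, q,
    n_used, de (q < alpha).  The EB fit and BH adjustment run separately
    within the complete and partial tiers.  Selective proteins carry a
    reported log2fc (from normalized values, for ranking/plotting) but no
    test statistics.
    """
    cond_a, cond_b = contrast
    status = classify_testability(matrix, contrast, paired, min_bio=min_bio,
                                  min_pairs=min_pairs, min_samples=min_samples)
    cols_a = matrix.samples_for(cond_a)
    cols_b = matrix.samples_for(cond_b)

    out = pd.DataFrame(index=matrix.values.index)
    out["contrast"] = f"{cond_a}_vs_{cond_b}"
    out["status"] = status["status"]
    out["tier"] = status["tier"]
    for col in ("log2fc", "sg_sq", "t_mod", "p", "q"):
        out[col] = np.nan
    out["dg"] = 0
    out["n_used"] = 0

    tested_ids = status.index[status["status"] == STATUS_TESTED]
    rows = {}
    for pid in tested_ids:
        usable = status.loc[pid, "usable"]
        fc, s2, dg, c = effect_and_variance(matrix, pid, contrast, paired,
                                            usable)
        rows[pid] = (fc, s2, dg, c, len(usable))
    for pid, (fc, s2, dg, c, n_used) in rows.items():
        out.loc[pid, ["log2fc", "sg_sq"]] = (fc, s2)
        out.loc[pid, "dg"] = dg
        out.loc[pid, "n_used"] = n_used

    for tier in (TIER_COMPLETE, TIER_PARTIAL):
        ids = [pid for pid in tested_ids if status.loc[pid, "tier"] == tier]
        if not ids:
            continue
        fc = out.loc[ids, "log2fc"].to_numpy()
        s2 = out.loc[ids, "sg_sq"].to_numpy()
        dg = out.loc[ids, "dg"].to_numpy(dtype=float)
        c = np.array([rows[pid][3] for pid in ids])
        hyper = fit_eb_hyperparams(s2, dg)
        t, p = moderated_t(fc, s2, dg, c, hyper)
        out.loc[ids, "t_mod"] = t
        out.loc[ids, "p"] = p
        out.loc[ids, "q"] = bh_adjust(p)

    # reported (untested) fold change for selectively expressed proteins
    selective = out["status"].str.startswith("selective_in_")
    if selective.any():
        mean_a = matrix.values.loc[selective, cols_a].mean(axis=1)
        mean_b = matrix.values.loc[selective, cols_b].mean(axis=1)
        out.loc[selective, "log2fc"] = mean_a - mean_b

    out["de"] = out["q"] < alpha
    out.index.name = "protein_id"
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    cols = ["contrast", "status", "tier", "log2fc", "sg_sq", "dg", "t_mod",
            "p", "q", "n_used", "de"]
    de[cols].to_csv(path, sep="\t")
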