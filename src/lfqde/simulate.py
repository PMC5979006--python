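"""Synthetic LFQ proteomics experiments with matched transcript summaries.

The generator emulates the statistical structure of a paired label-free
experiment on polarizing T helper cell subsets: 4 conditions x 3 biological
cultures x 3 technical MS runs, ~4,000 protein groups whose baseline
abundances span >= 6 orders of magnitude, intensity-dependent nondetection
(missing not at random: low-abundance proteins drop out more), a small set
of proteins expressed in a single condition only, and a transcript
differential-expression summary whose fold changes correlate with the
protein fold changes among shared-DE features at a configurable level.

The latent model per protein g and MS run r is

    L[g, r] = baseline[g] + effect[g, cond(r)] + culture[g, cult(r)] + eps

with eps ~ N(0, tech_sd[g]^2); the observed intensity is 2**L when the run
detects the protein (probability logistic in L) and 0 otherwise.  The
culture random effect is shared by all conditions of a culture, which is
what makes the paired design informative.

All randomness flows from a single seed through spawned substreams, so the
same configuration and seed reproduce the tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .ingest import RunIntensityTable

DEFAULT_CONDITIONS = ("Thp", "Th0", "Th17", "iTreg")


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the experimental design being emulated: 4 conditions x
    3 cultures x 3 technical replicates, 4,000 proteins, baseline log2
    abundance ~ N(24, 6.6^2) (so the linear-scale span comfortably exceeds
    6 orders of magnitude), ~10% DE proteins per condition at |log2fc| =
    1.5, culture sd 1.5 and technical sd 0.8 on the log2 scale (within-
    condition replicate correlations ~0.9-0.95 after median summarization),
    logistic dropout centred at log2 intensity 15 with scale 1.2 (~11%
    overall missingness, concentrated in the low-abundance tail), ~1%
    selectively expressed proteins, and a 0.65 protein-mRNA fold-change
    correlation among shared-DE features.
    """

    n_proteins: int = 4000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_cultures: int = 3
    n_tech: int = 3
    baseline_mean: float = 24.0
    baseline_sd: float = 6.6
    de_fraction: float = 0.10
    effect_size: float = 1.5
    culture_sd: float = 1.5
    tech_sd: float = 0.8
    tech_sd_dispersion: float = 0.2  # lognormal sigma of per-protein tech sd
    dropout_mid: float = 15.0       # log2 intensity of 50% detection
    dropout_scale: float = 1.2      # logistic scale; <=0 disables dropout
    selective_fraction: float = 0.01
    rna_overlap: float = 0.97       # share of proteins with a transcript row
    rna_rho: float = 0.65           # fold-change correlation, shared-DE
    rna_de_given_protein_de: float = 0.35
    rna_only_de_fraction: float = 0.05
    rna_extra_genes: float = 0.05   # transcripts with no protein, as share of n
    rna_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "selective_fraction", "rna_overlap",
                     "rna_rho", "rna_de_given_protein_de",
                     "rna_only_de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1]")
        for name in ("baseline_sd", "culture_sd", "tech_sd",
                     "tech_sd_dispersion"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be nonnegative")
        if len(self.conditions) < 2:
            raise SimulationError("need at least 2 conditions")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    effects: pd.DataFrame            # protein x condition true log2 effects
    selective_condition: pd.Series   # protein -> condition or NaN
    baseline: pd.Series              # protein -> baseline log2 abundance
    rna_true_log2fc: pd.Series       # gene -> true transcript log2fc
    rna_de_label: pd.Series          # gene -> bool
    rna_contrast: tuple[str, str]
    dropout_mid: float
    dropout_scale: float

    def true_log2fc(self, contrast: tuple[str, str]) -> pd.Series:
        a, b = contrast
        return self.effects[a] - self.effects[b]

    def de_label(self, contrast: tuple[str, str]) -> pd.Series:
        return self.true_log2fc(contrast) != 0


def _primary_contrast(conditions: tuple[str, ...]) -> tuple[str, str]:
    if "Th17" in conditions and "Th0" in conditions:
        return ("Th17", "Th0")
    return (conditions[-1], conditions[0])


def generate_dataset(config: SimConfig
                     ) -> tuple[RunIntensityTable, pd.DataFrame,
                                pd.DataFrame, SyntheticTruth]:
    """Simulate one experiment.

    Returns (run intensity table, design table, transcript DE table,
    ground truth).  The transcript table describes the primary contrast
    (Th17 vs Th0 when both are present, else last vs first condition).
    """
    cfg = config
    n = cfg.n_proteins
    ss = np.random.SeedSequence(cfg.seed)
    (r_base, r_eff, r_cult, r_tech, r_drop, r_sel, r_rna) = [
        np.random.default_rng(s) for s in ss.spawn(7)]

    protein_ids = np.array([f"P{i:05d}" for i in range(n)])
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    baseline = r_base.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)

    # condition effects relative to the first condition
    effects = pd.DataFrame(0.0, index=protein_ids, columns=list(cfg.conditions))
    for cond in cfg.conditions[1:]:
        is_de = r_eff.random(n) < cfg.de_fraction
        signs = r_eff.choice([-1.0, 1.0], size=n)
        effects[cond] = np.where(is_de, signs * cfg.effect_size, 0.0)

    # selectively expressed proteins: on in one non-reference condition only
    selective_condition = pd.Series(np.nan, index=protein_ids, dtype=object)
    if cfg.selective_fraction > 0 and len(cfg.conditions) > 1:
        n_sel = int(round(cfg.selective_fraction * n))
        candidates = effects.index[(effects != 0).sum(axis=1) == 0]
        n_sel = min(n_sel, len(candidates))
        chosen = r_sel.choice(len(candidates), size=n_sel, replace=False)
        on_conds = r_sel.choice(cfg.conditions[1:], size=n_sel)
        for idx, cond in zip(candidates[chosen], on_conds):
            selective_condition.loc[idx] = cond

    # design
    rows = []
    for cond in cfg.conditions:
        for cult in range(1, cfg.n_cultures + 1):
            for rep in range(1, cfg.n_tech + 1):
                rows.append({"run": f"{cond}_c{cult}_r{rep}",
                             "condition": cond, "culture": f"c{cult}",
                             "tech_rep": rep})
    design = pd.DataFrame(rows)

    tech_sd = cfg.tech_sd * np.exp(
        r_tech.normal(0.0, cfg.tech_sd_dispersion, size=n)) \
        if cfg.tech_sd_dispersion > 0 else np.full(n, cfg.tech_sd)
    culture_eff = {f"c{c}": r_cult.normal(0.0, cfg.culture_sd, size=n)
                   for c in range(1, cfg.n_cultures + 1)}

    intens = pd.DataFrame(index=protein_ids)
    sel_mask = selective_condition.notna().to_numpy()
    sel_cond = selective_condition.to_numpy()
    # Nondetection is missing-not-at-random: the probability of detecting a
    # protein in a biological sample is logistic in that sample's latent
    # log2 abundance, and the decision is shared by the sample's technical
    # replicates (match-between-runs makes real technical replicates agree
    # on identification almost always).
    sample_detected = {}
    for cond in cfg.conditions:
        for c in range(1, cfg.n_cultures + 1):
            cult = f"c{c}"
            sample_latent = (baseline + effects[cond].to_numpy()
                             + culture_eff[cult])
            if cfg.dropout_scale > 0:
                p_detect = expit(
                    (sample_latent - cfg.dropout_mid) / cfg.dropout_scale)
                sample_detected[(cond, cult)] = r_drop.random(n) < p_detect
            else:
                sample_detected[(cond, cult)] = np.ones(n, dtype=bool)
    for _, row in design.iterrows():
        cond, cult = row["condition"], row["culture"]
        latent = (baseline + effects[cond].to_numpy()
                  + culture_eff[cult]
                  + r_tech.normal(0.0, 1.0, size=n) * tech_sd)
        detected = sample_detected[(cond, cult)].copy()
        off = sel_mask & (sel_cond != cond)
        detected &= ~off
        intens[row["run"]] = np.where(detected, np.exp2(latent), 0.0)

    if (intens.to_numpy().sum(axis=0) == 0).any():
        raise SimulationError("configuration produced an all-missing run")

    table = RunIntensityTable(
        intensities=intens,
        flags=pd.DataFrame(False, index=protein_ids,
                           columns=["only_by_site", "reverse", "contaminant"]),
        gene_ids=pd.Series(gene_ids, index=protein_ids),
    )

    rna, rna_truth = _generate_transcripts(cfg, protein_ids, gene_ids,
                                           effects, r_rna)
    truth = SyntheticTruth(
        effects=effects, selective_condition=selective_condition,
        baseline=pd.Series(baseline, index=protein_ids),
        rna_true_log2fc=rna_truth["true_log2fc"],
        rna_de_label=rna_truth["de_label"],
        rna_contrast=_primary_contrast(cfg.conditions),
        dropout_mid=cfg.dropout_mid, dropout_scale=cfg.dropout_scale)
    return table, design, rna, truth


def _generate_transcripts(cfg: SimConfig, protein_ids, gene_ids,
                          effects: pd.DataFrame, rng: np.random.Generator
                          ) -> tuple[pd.DataFrame, dict]:
    """Transcript DE summary for the primary contrast.

    Among genes whose protein is truly DE, a configurable share is also DE
    at the transcript level; their fold changes are drawn so the Pearson
    correlation with the protein fold changes equals ``rna_rho`` in
    expectation.  FDRs are drawn consistently with the DE labels.
    """
    a, b = _primary_contrast(cfg.conditions)
    prot_fc = (effects[a] - effects[b]).to_numpy()
    n = len(protein_ids)

    has_rna = rng.random(n) < cfg.rna_overlap
    prot_de = prot_fc != 0
    shared_de = has_rna & prot_de & (
        rng.random(n) < cfg.rna_de_given_protein_de)
    rna_only_de = has_rna & ~prot_de & (
        rng.random(n) < cfg.rna_only_de_fraction)

    true_fc = np.zeros(n)
    if shared_de.any():
        x = prot_fc[shared_de]
        sd = x.std() if x.std() > 0 else cfg.effect_size
        noise = rng.normal(0.0, 1.0, size=shared_de.sum())
        true_fc[shared_de] = (cfg.rna_rho * x
                              + np.sqrt(1 - cfg.rna_rho ** 2) * sd * noise)
    if rna_only_de.any():
        signs = rng.choice([-1.0, 1.0], size=rna_only_de.sum())
        true_fc[rna_only_de] = signs * cfg.effect_size

    de = shared_de | rna_only_de
    observed_fc = true_fc + rng.normal(0.0, 0.1, size=n)
    fdr = np.where(de, 10.0 ** rng.uniform(-6, np.log10(cfg.rna_alpha * 0.98),
                                           size=n),
                   rng.uniform(cfg.rna_alpha * 1.04, 1.0, size=n))
    mean_expr = np.exp2(rng.normal(5.0, 2.0, size=n))

    frames = [pd.DataFrame({
        "gene_id": gene_ids[has_rna],
        "log2fc": observed_fc[has_rna],
        "fdr": fdr[has_rna],
        "mean_expr": mean_expr[has_rna],
        "detected": True,
    })]
    n_extra = int(round(cfg.rna_extra_genes * n))
    if n_extra:
        frames.append(pd.DataFrame({
            "gene_id": [f"GX{i:05d}" for i in range(n_extra)],
            "log2fc": rng.normal(0.0, 0.3, size=n_extra),
            "fdr": rng.uniform(cfg.rna_alpha * 1.04, 1.0, size=n_extra),
            "mean_expr": np.exp2(rng.normal(5.0, 2.0, size=n_extra)),
            "detected": True,
        }))
    rna = pd.concat(frames, ignore_index=True)
    truth = {
        "true_log2fc": pd.Series(true_fc, index=gene_ids),
        "de_label": pd.Series(de, index=gene_ids),
    }
    return rna, truth


def generate_null_dataset(config: SimConfig):
    """Same generator with all true effects and selective calls removed."""
    return generate_dataset(replace(config, de_fraction=0.0,
                                    selective_fraction=0.0))


def generate_count_matrix(n_genes: int = 200, n_samples: int = 8,
                          seed: int = 0, library_size: int = 1_000_000
                          ) -> pd.DataFrame:
    """Raw transcript counts for exercising the cpm low-expression filter."""
    rng = np.random.default_rng(seed)
    mean = np.exp(rng.normal(3.0, 2.0, size=n_genes))
    counts = rng.poisson(mean[:, None] * rng.uniform(0.5, 1.5, size=n_samples),
                         size=(n_genes, n_samples))
    return pd.DataFrame(counts,
                        index=[f"G{i:05d}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


def evaluate_recovery(de: pd.DataFrame, truth: SyntheticTruth,
                      contrast: tuple[str, str], alpha: float = 0.05) -> dict:
    """Empirical FDR, power and sign accuracy of a DE table against truth.

    Computed over tested proteins: discoveries are q < alpha; power is the
    share of truly DE tested proteins discovered; sign accuracy is the share
    of true positives whose estimated fold change has the true sign.
    """
    tested = de[de["status"] == "tested"]
    missing = set(tested.index) - set(truth.effects.index)
    if missing:
        raise SimulationError(f"{len(missing)} proteins absent from truth")
    true_fc = truth.true_log2fc(contrast).loc[tested.index]
    is_de = (true_fc != 0).to_numpy()
    called = (tested["q"] < alpha).to_numpy()
    n_called = int(called.sum())
    false_disc = int((called & ~is_de).sum())
    true_pos = called & is_de
    sign_ok = np.sign(tested["log2fc"].to_numpy()) == np.sign(
        true_fc.to_numpy())
    return {
        "n_tested": int(len(tested)),
        "n_true_de": int(is_de.sum()),
        "n_called": n_called,
        "fdr": false_disc / max(1, n_called),
        "power": float(true_pos.sum() / max(1, is_de.sum())),
        "sign_accuracy": float(sign_ok[true_pos].mean()) if true_pos.any()
        else float("nan"),
    }


# ---------------------------------------------------------------------------
# writers emitting the dialects the ingest module reads


def write_dataset(table: RunIntensityTable, design: pd.DataFrame,
                  rna: pd.DataFrame, out_dir) -> dict:
    """Write proteinGroups/design/transcript TSVs; returns the paths."""
    from pathlib import Path

    from .ingest import write_protein_groups

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": out / "proteinGroups.tsv",
        "design": out / "design.tsv",
        "transcripts": out / "transcripts.tsv",
    }
    write_protein_groups(table, paths["protein_groups"])
    design.to_csv(paths["design"], sep="\t", index=False)
    rna.to_csv(paths["transcripts"], sep="\t", index=False)
    return paths
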