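import numpy as np
import pandas as pd
import pytest

from lfqde.ingest import RunIntensityTable
from lfqde.preprocess import SampleMatrix


def make_table(values: np.ndarray, runs: list[str] | None = None,
               flags: np.ndarray | None = None) -> RunIntensityTable:
    """RunIntensityTable from a dense array (proteins x runs)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    pids = [f"P{i:03d}" for i in range(n)]
    runs = runs or [f"r{j}" for j in range(m)]
    if flags is None:
        flags = np.zeros((n, 3), dtype=bool)
    return RunIntensityTable(
        intensities=pd.DataFrame(values, index=pids, columns=runs),
        flags=pd.DataFrame(flags, index=pids,
                           columns=["only_by_site", "reverse", "contaminant"]),
        gene_ids=pd.Series([f"G{i:03d}" for i in range(n)], index=pids),
    )


def make_matrix(values: np.ndarray, conditions: list[str],
                cultures: list[str], detected: np.ndarray | None = None,
                is_log: bool = True) -> SampleMatrix:
    """SampleMatrix from a dense array with explicit sample annotations."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    assert len(conditions) == len(cultures) == m
    pids = [f"P{i:03d}" for i in range(n)]
    cols = [f"{c}:{k}" for c, k in zip(conditions, cultures)]
    if detected is None:
        detected = np.ones((n, m), dtype=bool)
    info = pd.DataFrame({"condition": conditions, "culture": cultures},
                        index=cols)
    return SampleMatrix(
        values=pd.DataFrame(values, index=pids, columns=cols),
        detected=pd.DataFrame(np.asarray(detected, dtype=bool), index=pids,
                              columns=cols),
        sample_info=info, is_log=is_log)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paired_design() -> pd.DataFrame:
    rows = []
    for cond in ("Th0", "Th17"):
        for cult in ("c1", "c2", "c3"):
            for rep in (1, 2, 3):
                rows.append({"run": f"{cond}_{cult}_r{rep}",
                             "condition": cond, "culture": cult,
                             "tech_rep": rep})
    return pd.DataFrame(rows)
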