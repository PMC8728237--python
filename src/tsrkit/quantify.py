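"""tsRNA abundance quantification and cross-cohort normalization.

Within a sample, abundance is expressed in reads per million tRNA-mapped
reads, RPM = 1e6 * C / N. For pooled (pan-cohort) analyses the RPM values
are made comparable across cohorts by a rank-based inverse-Gaussian
transformation scaled to [-1, 1] with a zero median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger("tsrkit.quantify")

#: rank offset of the inverse-normal transform: z_i = Phi^-1((r_i - OFFSET)/m)
RANK_OFFSET = 0.5


def compute_rpm(C: int, N: int) -> float:
    """Reads per million tRNA-mapped reads for one tsRNA."""
    if N < 0:
        raise ValueError("N must be non-negative")
    if C > N:
        raise ValueError(f"tsRNA count C={C} exceeds total tRNA-mapped count N={N}")
    if N == 0:
        logger.warning("N = 0 tRNA-mapped reads; RPM reported as 0")
        return 0.0
    return 1e6 * C / N


def rank_inverse_gaussian(values) -> np.ndarray:
    """Rank-based inverse-Gaussian transform, scaled to [-1, 1].

    z_i = Phi^-1((r_i - 0.5)/m) with average ranks r_i among the m values,
    then divided by max |z|. A constant input has no ranks to spread and is
    returned as the zero vector with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    r = rankdata(x, method="average")
    z = norm.ppf((r - RANK_OFFSET) / x.size)
    scale = np.max(np.abs(z))
    if scale == 0.0:
        logger.warning("all values identical; normalized vector is zero")
        return np.zeros_like(x)
    return z / scale


def build_expression_matrix(sample_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """tsRNA x sample RPM matrix from per-sample {tsRNA name: count} maps.

    N per sample is the total tRNA-mapped count, i.e. the sum of the
    sample's tsRNA counts.
    """
    samples = sorted(sample_counts)
    names = sorted({n for cts in sample_counts.values() for n in cts})
    mat = pd.DataFrame(0.0, index=names, columns=samples)
    for sample in samples:
        cts = sample_counts[sample]
        N = sum(cts.values())
        for name in names:
            mat.loc[name, sample] = compute_rpm(cts.get(name, 0), N) if N else 0.0
    return mat


def normalize_matrix(rpm: pd.DataFrame) -> pd.DataFrame:
    """Apply the rank-based inverse-Gaussian transform to each tsRNA row."""
    out = rpm.copy()
    for name in rpm.index:
        out.loc[name] = rank_inverse_gaussian(rpm.loc[name].to_numpy())
    return out


def group_summary(rpm: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Per-group mean/median RPM summary (tabular stand-in for expression plots)."""
    records = []
    for name in rpm.index:
        for group in sorted(set(groups.values())):
            cols = [s for s in rpm.columns if groups.get(s) == group]
            vals = rpm.loc[name, cols].to_numpy(dtype=float)
            records.append({
                "tsrna_name": name,
                "group": group,
                "n_samples": len(cols),
                "mean_rpm": float(np.mean(vals)) if len(cols) else np.nan,
                "median_rpm": float(np.median(vals)) if len(cols) else np.nan,
            })
    return pd.DataFrame.from_records(records)
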