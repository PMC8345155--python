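"""Two-step peptide-marker selection.

Step 1 compares case (HCC) against all non-case samples per peptide with a
Wilcoxon rank-sum test and keeps peptides whose Benjamini–Hochberg-adjusted
p-value is below ``alpha``.  Step 2 computes, among the survivors only, the
Spearman rank correlation of amplitude with the ordinal disease grade
(0 = non-cirrhotic, 1 = cirrhosis, 2 = HCC), BH-adjusts those p-values
within the survivors, and keeps peptides with adjusted p < alpha and
|rho| strictly above ``rho_threshold``.

Zeros (non-detections) enter the rank statistics as exact ties at the
minimum — absence is informative.  All statistics are rank-based and hence
invariant under monotone amplitude transforms such as ln(1+a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import PeakMatrix, SampleRecord, case_mask, grades


@dataclass(frozen=True)
class SelectionConfig:
    """Selection thresholds.

    min_frequency: detection-fraction threshold (kept if fraction >= it).
    alpha: BH-adjusted p cutoff used in both steps (strict <).
    rho_threshold: absolute Spearman cutoff (strict >).
    wilcoxon_exact_max_n: exact rank-sum enumeration when both groups are
      at most this size and there are no ties.
    spearman_exact_max_n: exact permutation p when n is at most this size.
    """

    min_frequency: float = 0.20
    alpha: float = 0.05
    rho_threshold: float = 0.3
    wilcoxon_exact_max_n: int = 10
    spearman_exact_max_n: int = 7

    def __post_init__(self) -> None:
        for name in ("min_frequency", "alpha", "rho_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class MarkerPanel:
    """Result of the two-step selection: ordered marker ids plus per-peptide
    statistics for every peptide that entered step 1 (``stats``; the
    ``selected`` column marks panel members)."""

    peptide_ids: list
    stats: pd.DataFrame

    def __len__(self) -> int:
        return len(self.peptide_ids)


def frequency_filter(peaks: PeakMatrix, min_frequency: float = 0.20) -> PeakMatrix:
    """Keep peptides detected (amplitude > 0) in at least ``min_frequency``
    of samples (>= on the exact fraction)."""
    freq = peaks.detection_frequency()
    keep = freq.index[freq >= min_frequency]
    return peaks.subset_peptides(list(keep))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Mid-ranks for ties; exact null enumeration when both groups have at
    most ``exact_max_n`` observations and there are no ties, otherwise the
    normal approximation with tie correction.  Returns (U statistic of the
    first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def _spearman_exact_p(a_rank: np.ndarray, g_rank: np.ndarray, rho_obs: float) -> float:
    n = len(a_rank)
    count = 0
    total = 0
    sa = a_rank - a_rank.mean()
    sg = g_rank - g_rank.mean()
    denom = math.sqrt((sa**2).sum() * (sg**2).sum())
    thresh = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        rho = float((sa[list(perm)] * sg).sum()) / denom
        count += abs(rho) >= thresh
        total += 1
    return count / total


def spearman_vs_grade(
    amplitudes: Sequence[float], grade: Sequence[int], exact_max_n: int = 7
) -> tuple[float, float]:
    """Spearman rank correlation of amplitudes against the ordinal grade.

    rho is the Pearson correlation of mid-ranks.  The p-value is exact (full
    permutation enumeration) for n <= ``exact_max_n`` and the t
    approximation otherwise.  Constant amplitudes (or a single grade) make
    rho undefined: returns (nan, nan).
    """
    a = np.asarray(amplitudes, dtype=float)
    g = np.asarray(grade, dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(g)) < 2:
        raise ValueError("need at least 2 distinct grades")
    if len(np.unique(a)) < 2:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, g)
    if len(a) <= exact_max_n:
        p = _spearman_exact_p(stats.rankdata(a), stats.rankdata(g), rho)
    return float(rho), float(p)


def _group_stats(values: np.ndarray) -> tuple[float, float, float]:
    """All-sample mean, SD (ddof 1) and detection frequency (%) of one group."""
    mean = float(values.mean()) if values.size else float("nan")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    freq = float((values > 0).mean() * 100) if values.size else float("nan")
    return mean, sd, freq


def select_markers(
    peaks: PeakMatrix,
    records: Sequence[SampleRecord],
    config: SelectionConfig = SelectionConfig(),
) -> MarkerPanel:
    """Run the two-step selection on a labeled peak matrix.

    Requires both case and control samples and at least two grades.
    Returns the panel together with the full per-peptide statistics table
    (Wilcoxon p and BH-adjusted p, single-peptide AUC, Spearman rho and its
    adjusted p for step-1 survivors, per-group mean/SD/frequency).
    """
    if [r.sample_id for r in records] != peaks.sample_ids:
        raise ValueError("records must align with the peak-matrix samples")
    is_case = case_mask(records)
    if is_case.all() or not is_case.any():
        raise ValueError("need both case (HCC) and control samples")
    grade = grades(records)
    if len(np.unique(grade)) < 2:
        raise ValueError("need at least 2 distinct grades")

    amp = peaks.amplitudes.to_numpy(dtype=float)
    peptide_ids = peaks.peptide_ids
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())

    rows = []
    for j, pid in enumerate(peptide_ids):
        x = amp[is_case, j]
        y = amp[~is_case, j]
        u_stat, p = wilcoxon_rank_sum(x, y, exact_max_n=config.wilcoxon_exact_max_n)
        auc = u_stat / (n_case * n_ctrl)
        g_mean = {}
        for label, mask in (
            ("nonlc", grade == 0),
            ("lc", grade == 1),
            ("hcc", grade == 2),
        ):
            m, s, f = _group_stats(amp[mask, j])
            g_mean[f"mean_{label}"], g_mean[f"sd_{label}"], g_mean[f"freq_{label}"] = m, s, f
        rows.append({"peptide_id": pid, "p_value": p, "auc": auc, **g_mean})
    table = pd.DataFrame(rows).set_index("peptide_id", drop=False)
    table["p_adj"] = bh_adjust(table["p_value"].to_numpy())

    step1 = table.index[table["p_adj"] < config.alpha]
    table["rho"] = np.nan
    table["rho_p"] = np.nan
    table["rho_p_adj"] = np.nan
    if len(step1):
        rhos, ps = [], []
        for pid in step1:
            rho, p = spearman_vs_grade(
                peaks.amplitudes[pid].to_numpy(), grade,
                exact_max_n=config.spearman_exact_max_n,
            )
            rhos.append(rho)
            ps.append(p)
        table.loc[step1, "rho"] = rhos
        table.loc[step1, "rho_p"] = ps
        defined = step1[np.isfinite(ps)]
        if len(defined):
            table.loc[defined, "rho_p_adj"] = bh_adjust(
                table.loc[defined, "rho_p"].to_numpy()
            )
    selected = (
        (table["p_adj"] < config.alpha)
        & (table["rho_p_adj"] < config.alpha)
        & (table["rho"].abs() > config.rho_threshold)
    ).fillna(False)
    table["selected"] = selected
    ordered = [pid for pid in peptide_ids if selected.loc[pid]]
    return MarkerPanel(peptide_ids=ordered, stats=table)
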