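"""End-to-end orchestration of the analysis stages.

``run_discovery`` chains normalization (optional) -> detection-frequency
filter -> two-step marker selection -> class-weighted SVM training ->
leave-one-out ROC -> Youden thresholding on a labeled discovery cohort.
``run_validation`` scores an independent cohort with a frozen model,
evaluates ROC at the frozen threshold, adjusts for age/sex and stratifies
survival by test result.  ``run_protease`` maps sequence annotations to
cleavage sites, associates proteases and computes activity fold changes.

Every stage logs its input/output dimensions through the ``uropep`` logger,
and all results are deterministic given the inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .calibration import normalize_amplitudes
from .classify import (
    ClassifierModel,
    CovariateAdjustment,
    ROCResult,
    SVMConfig,
    adjust_covariates,
    loo_cross_validate,
    membership_scores,
    roc_analysis,
    train_svm,
    youden_threshold,
)
from .proteases import (
    ProteaseActivityTable,
    activity_scores,
    associate_proteases,
    fold_change_stats,
    reconstruct_sites,
)
from .selection import MarkerPanel, SelectionConfig, frequency_filter, select_markers
from .survival import HazardResult, apply_horizon, hazard_ratio
from .types import PeakMatrix, SampleRecord, case_mask

log = logging.getLogger("uropep")


class PipelineError(RuntimeError):
    """A stage could not proceed; the message names the stage."""


@dataclass
class DiscoveryResult:
    panel: MarkerPanel
    model: ClassifierModel
    loo_scores: pd.Series
    roc: ROCResult
    youden_threshold: float
    youden_j: float

    def summary(self) -> str:
        lines = [
            f"markers selected: {len(self.panel)}",
            f"LOO AUC: {self.roc.auc:.3f} "
            f"(95% CI {self.roc.auc_ci_95[0]:.3f}-{self.roc.auc_ci_95[1]:.3f})",
            f"Youden threshold: {self.youden_threshold:.4f} (J = {self.youden_j:.3f})",
            f"sensitivity at threshold: {self.roc.sensitivity:.3f}",
            f"specificity at threshold: {self.roc.specificity:.3f}",
        ]
        return "\n".join(lines)


def run_discovery(
    peaks: PeakMatrix,
    records: Sequence[SampleRecord],
    selection: SelectionConfig = SelectionConfig(),
    svm: SVMConfig = SVMConfig(),
    internal_standards: pd.Series | None = None,
    normalization_mode: str = "local",
) -> DiscoveryResult:
    """Discovery phase: select a marker panel and train/evaluate the classifier.

    The model's decision threshold is set to the Youden optimum of the
    leave-one-out scores, and the reported ROC is computed on those
    cross-validated scores.
    """
    n_in = peaks.shape[0]
    if internal_standards is not None:
        peaks = normalize_amplitudes(peaks, internal_standards, mode=normalization_mode)
        log.info("normalized %d samples against %d standards", n_in, len(internal_standards))
    filtered = frequency_filter(peaks, selection.min_frequency)
    log.info(
        "frequency filter: %d -> %d peptides (threshold %.0f%%)",
        peaks.shape[1], filtered.shape[1], 100 * selection.min_frequency,
    )
    panel = select_markers(filtered, records, selection)
    log.info("marker selection: %d peptides selected", len(panel))
    if len(panel) == 0:
        raise PipelineError("marker selection: no markers selected")
    model = train_svm(filtered, records, panel.peptide_ids, svm)
    loo = loo_cross_validate(filtered, records, panel.peptide_ids, svm)
    labels = case_mask(records)
    thr, j = youden_threshold(loo.to_numpy(), labels)
    model.threshold = thr
    roc = roc_analysis(loo.to_numpy(), labels, thr)
    log.info("LOO AUC %.3f, Youden threshold %.4f", roc.auc, thr)
    return DiscoveryResult(
        panel=panel, model=model, loo_scores=loo, roc=roc,
        youden_threshold=thr, youden_j=j,
    )


@dataclass
class ValidationResult:
    scores: pd.Series
    roc: ROCResult
    adjustment: CovariateAdjustment | None
    survival: HazardResult | None
    n_positive: int
    n_negative: int

    def summary(self) -> str:
        lines = [
            f"validation AUC: {self.roc.auc:.3f} "
            f"(95% CI {self.roc.auc_ci_95[0]:.3f}-{self.roc.auc_ci_95[1]:.3f})",
            f"sensitivity: {100 * self.roc.sensitivity:.1f}%  "
            f"specificity: {100 * self.roc.specificity:.1f}%  "
            f"(threshold {self.roc.threshold:.4f})",
        ]
        if self.adjustment is not None:
            lines.append(
                f"age/sex-adjusted AUC: {self.adjustment.auc_adjusted:.3f} "
                f"(paired DeLong p = {self.adjustment.delong_p:.4f})"
            )
        if self.survival is not None:
            lines.append(
                f"hazard ratio (positive vs negative test): "
                f"{self.survival.hazard_ratio:.2f} "
                f"(95% CI {self.survival.ci_95[0]:.2f}-{self.survival.ci_95[1]:.2f}, "
                f"log-rank p = {self.survival.logrank_p:.2g})"
            )
        return "\n".join(lines)


def run_validation(
    model: ClassifierModel,
    peaks: PeakMatrix,
    records: Sequence[SampleRecord],
    horizon_days: float = 500.0,
) -> ValidationResult:
    """Score an independent cohort with a frozen model.

    ROC is evaluated at the model's frozen threshold; classification is
    additionally adjusted for age and sex (skipped with a warning when ages
    are missing), and overall survival is stratified by test result
    (skipped with a warning when survival data are missing).
    """
    missing = [p for p in model.panel if p not in peaks.amplitudes.columns]
    if missing:
        raise PipelineError(f"validation: panel peptides missing from cohort: {missing}")
    scores = membership_scores(model, peaks)
    labels = case_mask(records)
    roc = roc_analysis(scores.to_numpy(), labels, model.threshold)

    ages = np.array([r.age for r in records], dtype=float)
    adjustment = None
    if np.isnan(ages).any():
        warnings.warn("age missing for some samples; covariate adjustment skipped")
    else:
        adjustment = adjust_covariates(scores.to_numpy(), records)

    times = np.array([r.survival_days for r in records], dtype=float)
    surv = None
    positive = scores.to_numpy() >= model.threshold
    if np.isnan(times).any():
        warnings.warn("survival data missing; survival stratification skipped")
    else:
        events = np.array([r.event for r in records], dtype=bool)
        t, e = apply_horizon(times, events, horizon_days)
        try:
            surv = hazard_ratio(
                t[positive], e[positive], t[~positive], e[~positive],
                horizon_days=horizon_days,
            )
        except ValueError as err:
            warnings.warn(f"hazard ratio unavailable: {err}")
    return ValidationResult(
        scores=scores, roc=roc, adjustment=adjustment, survival=surv,
        n_positive=int(positive.sum()), n_negative=int((~positive).sum()),
    )


@dataclass
class ProteaseResult:
    substrate_map: dict[str, set[str]]
    activity: ProteaseActivityTable
    fold_changes: pd.DataFrame

    def summary(self) -> str:
        lines = [f"{len(self.substrate_map)} proteases with substrates"]
        for _, row in self.fold_changes.iterrows():
            lines.append(
                f"  {row['protease']}: fold {row['fold_change']:.2f} "
                f"(p = {row['p']:.3g}, adj {row['p_adj']:.3g})"
            )
        return "\n".join(lines)


def run_protease(
    peaks: PeakMatrix,
    records: Sequence[SampleRecord],
    substrate_map: Mapping[str, set[str]] | None = None,
    annotations=None,
    rules=None,
) -> ProteaseResult:
    """Protease-activity stage.

    Either pass a curated ``substrate_map`` directly (default: the bundled
    marker-panel associations) or pass ``annotations`` plus specificity
    ``rules`` to reconstruct cleavage sites and derive the map.  Substrates
    absent from the matrix are dropped with a warning (proteases left with
    no substrate are omitted).
    """
    if substrate_map is None:
        if annotations is not None and rules is not None:
            sites = reconstruct_sites(annotations)
            substrate_map = associate_proteases(sites, rules)
        else:
            substrate_map = _io.marker_association_map()
    present = set(map(str, peaks.peptide_ids))
    usable: dict[str, set[str]] = {}
    for protease, subs in substrate_map.items():
        subs = set(map(str, subs))
        absent = subs - present
        if absent:
            warnings.warn(
                f"{protease}: substrate peptide(s) {sorted(absent)} absent "
                f"from matrix; dropped"
            )
        kept = subs & present
        if kept:
            usable[protease] = kept
    if not usable:
        return ProteaseResult(
            substrate_map={}, activity=ProteaseActivityTable(
                activity=pd.DataFrame(index=peaks.amplitudes.index), substrate_map={}
            ),
            fold_changes=pd.DataFrame(
                columns=["protease", "case_mean", "case_sd", "control_mean",
                         "control_sd", "fold_change", "p", "undefined", "p_adj"]
            ),
        )
    table = activity_scores(peaks, usable)
    folds = fold_change_stats(table, records)
    log.info("protease activity: %d proteases scored", len(usable))
    return ProteaseResult(substrate_map=usable, activity=table, fold_changes=folds)
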