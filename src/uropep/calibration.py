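"""Mass/migration-time calibration and internal-standard amplitude
normalization of CE-MS peak lists.

Masses are calibrated by a single global ordinary-least-squares fit of
reference vs observed mass; migration times by a locally linear
(nearest-neighbour, tricube-weighted) fit whose resulting mapping is forced
monotone non-decreasing.  Signal amplitudes are normalized per sample
against a panel of ubiquitously detected "internal standard" peptides: the
sample's log amplitudes of the detected standards are regressed on the log
reference amplitudes (locally linear by default, plain OLS in ``global``
mode) and the inverse mapping is applied to all non-zero amplitudes of that
sample.  This corrects dilution and analytical response in a single step;
zeros (non-detections) are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PeakMatrix


@dataclass
class ReferenceSet:
    """Calibration references.

    ``internal_standards`` maps standard peptide id -> reference amplitude
    (ion counts); ``mass_refs``/``time_refs`` are (observed, reference)
    pairs in Da / minutes.
    """

    internal_standards: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    mass_refs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    time_refs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _check_pairs(refs: np.ndarray, what: str) -> np.ndarray:
    refs = np.asarray(refs, dtype=float)
    if refs.ndim != 2 or refs.shape[1] != 2 or refs.shape[0] < 2:
        raise ValueError(f"need >= 2 (observed, reference) {what} pairs")
    if not np.all(np.isfinite(refs)):
        raise ValueError(f"non-finite {what} reference values")
    return refs


def calibrate_mass(peaks: PeakMatrix, mass_refs: np.ndarray) -> PeakMatrix:
    """Global linear mass calibration: fit ``reference = a*observed + b`` by
    OLS over the reference pairs and map every peptide mass through it."""
    refs = _check_pairs(mass_refs, "mass")
    a, b = np.polyfit(refs[:, 0], refs[:, 1], deg=1)
    info = peaks.peptide_info.copy()
    info["mass"] = a * info["mass"].to_numpy() + b
    return peaks.with_peptide_info(info)


def _local_linear(x_ref: np.ndarray, y_ref: np.ndarray, x_query: np.ndarray,
                  span: float) -> np.ndarray:
    """Tricube-weighted nearest-neighbour linear fit evaluated at x_query.

    ``span`` is the fraction of reference points entering each local fit;
    span >= 1 (or fewer than 3 references) degrades to a single global OLS.
    """
    n = len(x_ref)
    k = int(np.ceil(span * n))
    if k >= n or n < 3:
        a, b = np.polyfit(x_ref, y_ref, deg=1)
        return a * x_query + b
    k = max(k, 2)
    out = np.empty_like(x_query, dtype=float)
    order = np.argsort(x_ref)
    xs, ys = x_ref[order], y_ref[order]
    for i, xq in enumerate(x_query):
        d = np.abs(xs - xq)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        w = np.maximum(w, 1e-9)
        W = np.sqrt(w)
        A = np.stack([np.ones(k), xs[idx]], axis=1) * W[:, None]
        coef, *_ = np.linalg.lstsq(A, ys[idx] * W, rcond=None)
        out[i] = coef[0] + coef[1] * xq
    return out


def calibrate_time(peaks: PeakMatrix, time_refs: np.ndarray, span: float = 0.5) -> PeakMatrix:
    """Local linear migration-time calibration.

    Each peptide's observed CE time is mapped through a nearest-neighbour
    tricube-weighted linear fit of reference vs observed time; the fitted
    mapping is forced monotone non-decreasing in observed time.
    """
    refs = _check_pairs(time_refs, "time")
    times = peaks.peptide_info["ce_time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("non-finite CE times in peak matrix")
    order = np.argsort(times)
    fitted = _local_linear(refs[:, 0], refs[:, 1], times[order], span)
    fitted = np.maximum.accumulate(fitted)  # enforce monotone mapping
    out = np.empty_like(times)
    out[order] = fitted
    info = peaks.peptide_info.copy()
    info["ce_time"] = out
    return peaks.with_peptide_info(info)


def _invertible_curve(x: np.ndarray, y_fit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted, strictly increasing (x, y) pairs of a fitted monotone curve."""
    order = np.argsort(x)
    xs, ys = x[order], y_fit[order]
    ys = np.maximum.accumulate(ys)
    # collapse flat segments so interpolation of the inverse is well defined
    keep = np.concatenate([[True], np.diff(ys) > 1e-12])
    return xs[keep], ys[keep]


def _apply_inverse(ln_amp: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Invert the ln(observed) = g(ln(reference)) curve by interpolation,
    extrapolating linearly with the end-segment slopes."""
    if len(xs) < 2:
        raise ValueError("degenerate normalization curve (constant fit)")
    corrected = np.interp(ln_amp, ys, xs)
    lo_slope = (xs[1] - xs[0]) / (ys[1] - ys[0])
    hi_slope = (xs[-1] - xs[-2]) / (ys[-1] - ys[-2])
    below = ln_amp < ys[0]
    above = ln_amp > ys[-1]
    corrected[below] = xs[0] + (ln_amp[below] - ys[0]) * lo_slope
    corrected[above] = xs[-1] + (ln_amp[above] - ys[-1]) * hi_slope
    return corrected


def normalize_amplitudes(
    peaks: PeakMatrix,
    internal_standards: pd.Series,
    mode: str = "local",
    span: float = 0.5,
    min_detected: int = 15,
) -> PeakMatrix:
    """Internal-standard amplitude normalization, one regression per sample.

    For each sample, ln(observed amplitude) of the detected standards is
    regressed on ln(reference amplitude) (tricube-weighted local linear fit
    in ``local`` mode, plain OLS in ``global`` mode) and the inverse of the
    fitted mapping is applied to every non-zero amplitude of the sample.
    Zeros stay zero.  Samples detecting fewer than ``min_detected``
    standards are rejected.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    standards = internal_standards.astype(float)
    if (standards <= 0).any():
        raise ValueError("reference amplitudes must be positive")
    present = [p for p in standards.index if p in peaks.amplitudes.columns]
    if len(present) < 2:
        raise ValueError("need >= 2 internal standards present in the matrix")
    std_amp = peaks.amplitudes[present]
    detected_counts = (std_amp > 0).sum(axis=1)
    too_few = detected_counts[detected_counts < min_detected]
    if len(too_few):
        raise ValueError(
            "samples detect fewer than "
            f"{min_detected} internal standards: {list(too_few.index)}"
        )

    out = peaks.amplitudes.to_numpy(dtype=float).copy()
    for i, sample in enumerate(peaks.amplitudes.index):
        row = std_amp.loc[sample]
        det = row > 0
        x = np.log(standards[row.index[det]].to_numpy())   # ln reference
        y = np.log(row[det].to_numpy())                    # ln observed
        if mode == "global" or len(x) < 3:
            slope, intercept = np.polyfit(x, y, deg=1)
            if slope <= 0:
                raise ValueError(f"sample {sample!r}: non-increasing standards fit")
            nz = out[i] > 0
            out[i, nz] = np.exp((np.log(out[i, nz]) - intercept) / slope)
        else:
            y_fit = _local_linear(x, y, np.sort(x), span)
            xs, ys = _invertible_curve(np.sort(x), y_fit)
            nz = out[i] > 0
            out[i, nz] = np.exp(_apply_inverse(np.log(out[i, nz]), xs, ys))
    return peaks.with_amplitudes(
        pd.DataFrame(out, index=peaks.amplitudes.index, columns=peaks.amplitudes.columns)
    )
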