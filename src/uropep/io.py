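"""Readers/writers for peak lists, metadata, annotations, and bundled fixtures.

Peak lists are plain delimited text in two dialects:

* **wide** (canonical output): one row per peptide with columns
  ``peptide_id``, ``mass``, ``ce_time`` followed by one amplitude column per
  sample;
* **long**: columns ``peptide_id``, ``mass``, ``ce_time``, ``sample_id``,
  ``amplitude``; absent (sample, peptide) pairs decode to amplitude 0.

Delimiter is inferred from the extension (``.csv`` -> comma, else tab).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import MASS_WINDOW, PeakMatrix, SampleRecord, SequenceAnnotation, frame_to_records, records_to_frame

_FIXTURES = {"table1", "table2", "table3", "table4", "synthetic_demo_rules"}

_META_COLS = ("peptide_id", "mass", "ce_time")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), comment="#", **kwargs)


def read_peak_matrix(path, mass_window: tuple[float, float] | None = MASS_WINDOW) -> PeakMatrix:
    """Read a peak list (wide or long dialect) into a :class:`PeakMatrix`.

    Amplitudes must be >= 0 (0 = not detected); duplicate peptide ids and
    masses outside ``mass_window`` are rejected.  Pass ``mass_window=None``
    to disable the window check.
    """
    frame = _read_table(path, dtype={"peptide_id": str})
    required = set(_META_COLS)
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: peak list must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    is_long = {"sample_id", "amplitude"}.issubset(frame.columns)
    if is_long:
        pep = (
            frame[list(_META_COLS)]
            .drop_duplicates()
            .set_index("peptide_id")
        )
        if pep.index.duplicated().any():
            dups = pep.index[pep.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: conflicting mass/time for peptide ids {dups}")
        amp = frame.pivot_table(
            index="sample_id", columns="peptide_id", values="amplitude", fill_value=0.0
        )
        amp = amp.reindex(columns=pep.index, fill_value=0.0).astype(float)
        # preserve file order of samples
        amp = amp.loc[pd.unique(frame["sample_id"])]
    else:
        if frame["peptide_id"].duplicated().any():
            dups = frame["peptide_id"][frame["peptide_id"].duplicated()].tolist()
            raise ValueError(f"{path}: duplicate peptide ids {dups}")
        pep = frame[list(_META_COLS)].set_index("peptide_id")
        sample_cols = [c for c in frame.columns if c not in _META_COLS]
        amp = frame.set_index("peptide_id")[sample_cols].T.astype(float)
        amp.index.name = "sample_id"
    values = amp.to_numpy()
    bad = np.argwhere(~np.isfinite(values) | (values < 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: negative or non-finite amplitude for sample "
            f"{amp.index[i]!r}, peptide {amp.columns[j]!r}"
        )
    if mass_window is not None:
        lo, hi = mass_window
        outside = pep.index[(pep["mass"] < lo) | (pep["mass"] > hi)].tolist()
        if outside:
            raise ValueError(
                f"{path}: peptide mass outside [{lo}, {hi}] Da for ids {outside}"
            )
    return PeakMatrix(amp, pep)


def write_peak_matrix(peaks: PeakMatrix, path, dialect: str = "wide") -> None:
    """Write a peak list; ``dialect`` is ``wide`` (canonical) or ``long``."""
    path = Path(path)
    pep = peaks.peptide_info[["mass", "ce_time"]].reset_index()
    pep.columns = list(_META_COLS)
    if dialect == "wide":
        wide = pd.concat(
            [pep.set_index("peptide_id"), peaks.amplitudes.T], axis=1
        ).reset_index(names="peptide_id")
        wide.to_csv(path, sep=_sep(path), index=False)
    elif dialect == "long":
        long = (
            peaks.amplitudes.stack()
            .rename("amplitude")
            .reset_index()
            .rename(columns={"level_0": "sample_id", "level_1": "peptide_id"})
        )
        long.columns = ["sample_id", "peptide_id", "amplitude"]
        # dense output: explicit zeros keep never-detected peptides/samples
        # representable and make the round trip exact; sparse files (absent
        # rows decode to 0) remain readable
        long = long.merge(pep, on="peptide_id")
        long[["peptide_id", "mass", "ce_time", "sample_id", "amplitude"]].to_csv(
            path, sep=_sep(path), index=False
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sample_records(path) -> list[SampleRecord]:
    frame = _read_table(path, dtype={"sample_id": str})
    return frame_to_records(frame)


def write_sample_records(records: Sequence[SampleRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep=_sep(path), index=False)


def _annotation_from_row(row) -> SequenceAnnotation:
    def flank(v):
        return "" if pd.isna(v) else str(v)

    return SequenceAnnotation(
        peptide_id=str(row["peptide_id"]),
        protein=str(row["protein"]),
        aa_start=int(row["aa_start"]),
        aa_end=int(row["aa_end"]),
        sequence=str(row["sequence"]),
        n_flank=flank(row.get("n_flank", "")),
        c_flank=flank(row.get("c_flank", "")),
    )


def annotations_from_frame(frame: pd.DataFrame) -> list[SequenceAnnotation]:
    """Build annotations from a table; rows without a sequence are skipped."""
    out = []
    for _, row in frame.iterrows():
        seq = row.get("sequence")
        if pd.isna(seq) or str(seq) == "":
            continue
        out.append(_annotation_from_row(row))
    return out


def read_annotations(path) -> list[SequenceAnnotation]:
    """Read a sequence-annotation table.

    Expected columns: ``peptide_id, protein, aa_start, aa_end, sequence,
    n_flank, c_flank``.  Rows whose sequence field is empty (peptides that
    were never sequence-identified) are silently omitted.  Span/length
    mismatches and illegal residues raise ``ValueError``.
    """
    frame = _read_table(path, dtype={"peptide_id": str})
    required = {"peptide_id", "protein", "aa_start", "aa_end", "sequence"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: annotation table must have columns {sorted(required)}")
    return annotations_from_frame(frame)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled reference table by name.

    ``table1``: cohort demographics; ``table2``: the 31-marker discovery
    statistics; ``table3``: marker sequence annotation and curated protease
    associations; ``table4``: protease fold-change statistics;
    ``synthetic_demo_rules``: a synthetic demonstration specificity-rule set.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    ref = resources.files("uropep.fixtures") / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"peptide_id": str})


def marker_annotations() -> list[SequenceAnnotation]:
    """Sequence annotations of the marker panel (27 sequenced of 31 peptides)."""
    return annotations_from_frame(load_fixture("table3"))


def marker_association_map() -> dict[str, set[str]]:
    """Curated protease -> substrate-peptide-id map from the bundled panel table.

    A peptide is a substrate of a protease if the protease is associated
    with its N- or C-terminal cleavage site; a peptide matching at both
    termini is counted once.
    """
    frame = load_fixture("table3")
    mapping: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        for col in ("proteases_n", "proteases_c"):
            cell = row.get(col)
            if pd.isna(cell) or str(cell) == "":
                continue
            for protease in str(cell).split(";"):
                mapping.setdefault(protease.strip(), set()).add(str(row["peptide_id"]))
    return mapping
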