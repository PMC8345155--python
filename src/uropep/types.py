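"""Core domain types for urinary CE-MS peptidomics analysis.

The central container is :class:`PeakMatrix`, a dense samples x peptides
matrix of normalized signal amplitudes (ion counts) in which 0 encodes
"peptide not detected in this sample".  Non-detection is treated as an
informative tied-low value throughout the package, never as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Clinical groups.  Grading score used for monotone-trend marker selection:
#: HCC = 2, LC (liver cirrhosis) = 1, everything else (normal, NAFLD, NASH
#: without cirrhosis, other) = 0.
GROUPS = ("HCC", "LC", "NASH", "NAFLD", "NORMAL", "OTHER")

#: Analysis mass window in Da.
MASS_WINDOW = (800.0, 20000.0)


def grade_of(group: str) -> int:
    """Ordinal disease grade derived from the clinical group label."""
    if group == "HCC":
        return 2
    if group == "LC":
        return 1
    if group in GROUPS:
        return 0
    raise ValueError(f"unknown clinical group {group!r}")


@dataclass(frozen=True)
class Peptide:
    """A CE-MS detected peptide: identifier, monoisotopic mass, migration time."""

    peptide_id: str
    mass: float
    ce_time: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mass) or self.mass <= 0:
            raise ValueError(f"peptide {self.peptide_id}: invalid mass {self.mass}")
        if not np.isfinite(self.ce_time) or self.ce_time <= 0:
            raise ValueError(
                f"peptide {self.peptide_id}: invalid CE time {self.ce_time}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one urine sample/patient."""

    sample_id: str
    group: str
    age: float = float("nan")
    sex: str = "M"
    survival_days: float = float("nan")
    event: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"sample {self.sample_id}: unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sample {self.sample_id}: sex must be F or M")
        if not np.isnan(self.survival_days) and self.survival_days < 0:
            raise ValueError(f"sample {self.sample_id}: negative survival time")

    @property
    def grade(self) -> int:
        return grade_of(self.group)

    @property
    def is_case(self) -> bool:
        return self.group == "HCC"


class PeakMatrix:
    """Dense samples x peptides matrix of normalized amplitudes.

    Parameters
    ----------
    amplitudes
        DataFrame indexed by sample id with one column per peptide id.
        All entries must be finite and >= 0; 0 means "not detected".
    peptide_info
        DataFrame indexed by peptide id with columns ``mass`` and
        ``ce_time`` (additional columns are carried along untouched).
    """

    def __init__(self, amplitudes: pd.DataFrame, peptide_info: pd.DataFrame):
        amplitudes = amplitudes.copy()
        peptide_info = peptide_info.copy()
        if amplitudes.columns.duplicated().any():
            dups = amplitudes.columns[amplitudes.columns.duplicated()].tolist()
            raise ValueError(f"duplicate peptide ids: {dups}")
        if amplitudes.index.duplicated().any():
            dups = amplitudes.index[amplitudes.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not amplitudes.columns.equals(peptide_info.index):
            missing = amplitudes.columns.difference(peptide_info.index).tolist()
            extra = peptide_info.index.difference(amplitudes.columns).tolist()
            raise ValueError(
                f"peptide_info does not align with amplitude columns "
                f"(missing {missing}, extra {extra})"
            )
        values = amplitudes.to_numpy(dtype=float)
        if values.size and (not np.all(np.isfinite(values)) or (values < 0).any()):
            bad = np.argwhere(~np.isfinite(values) | (values < 0))[0]
            raise ValueError(
                f"negative or non-finite amplitude at sample "
                f"{amplitudes.index[bad[0]]!r}, peptide {amplitudes.columns[bad[1]]!r}"
            )
        for col in ("mass", "ce_time"):
            if col not in peptide_info.columns:
                raise ValueError(f"peptide_info lacks required column {col!r}")
        self.amplitudes = amplitudes
        self.peptide_info = peptide_info

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.amplitudes.index)

    @property
    def peptide_ids(self) -> list:
        return list(self.amplitudes.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitudes.shape

    def detection_frequency(self) -> pd.Series:
        """Fraction of samples in which each peptide has amplitude > 0."""
        if len(self.amplitudes) == 0:
            return pd.Series(0.0, index=self.amplitudes.columns)
        return (self.amplitudes > 0).mean(axis=0)

    # -- derived matrices ----------------------------------------------------
    def subset_peptides(self, peptide_ids: Sequence) -> "PeakMatrix":
        ids = list(peptide_ids)
        missing = [p for p in ids if p not in self.amplitudes.columns]
        if missing:
            raise KeyError(f"peptides not in matrix: {missing}")
        return PeakMatrix(self.amplitudes[ids], self.peptide_info.loc[ids])

    def subset_samples(self, sample_ids: Sequence) -> "PeakMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.amplitudes.index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return PeakMatrix(self.amplitudes.loc[ids], self.peptide_info)

    def with_amplitudes(self, amplitudes: pd.DataFrame) -> "PeakMatrix":
        return PeakMatrix(amplitudes, self.peptide_info)

    def with_peptide_info(self, peptide_info: pd.DataFrame) -> "PeakMatrix":
        return PeakMatrix(self.amplitudes, peptide_info)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakMatrix):
            return NotImplemented
        return self.amplitudes.equals(other.amplitudes) and self.peptide_info[
            ["mass", "ce_time"]
        ].equals(other.peptide_info[["mass", "ce_time"]])

    def __repr__(self) -> str:
        n_s, n_p = self.shape
        return f"PeakMatrix({n_s} samples x {n_p} peptides)"


@dataclass(frozen=True)
class SequenceAnnotation:
    """Amino-acid sequence assignment of a peptide within its parent protein.

    ``sequence`` uses the 20 standard one-letter residues plus lowercase
    ``p`` (hydroxyproline) and lowercase ``m`` (oxidized methionine).
    ``n_flank``/``c_flank`` hold up to four residues of the parent protein
    preceding/following the peptide; an empty flank marks a protein terminus.
    """

    peptide_id: str
    protein: str
    aa_start: int
    aa_end: int
    sequence: str
    n_flank: str = ""
    c_flank: str = ""

    VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "pm")

    def __post_init__(self) -> None:
        if self.aa_end - self.aa_start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.peptide_id}: span {self.aa_start}-{self.aa_end} "
                f"(length {self.aa_end - self.aa_start + 1}) does not match "
                f"sequence length {len(self.sequence)}"
            )
        for name, seq in (
            ("sequence", self.sequence),
            ("n_flank", self.n_flank),
            ("c_flank", self.c_flank),
        ):
            bad = set(seq) - self.VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"peptide {self.peptide_id}: illegal residue(s) "
                    f"{sorted(bad)} in {name}"
                )
        if not 0 <= len(self.n_flank) <= 4 or not 0 <= len(self.c_flank) <= 4:
            raise ValueError(f"peptide {self.peptide_id}: flank longer than 4")
        if not self.sequence:
            raise ValueError(f"peptide {self.peptide_id}: empty sequence")


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tabular view of sample records (indexed by sample id)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "group": r.group,
            "grade": r.grade,
            "age": r.age,
            "sex": r.sex,
            "survival_days": r.survival_days,
            "event": r.event,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.set_index("sample_id", drop=False)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    out = []
    for _, row in frame.iterrows():
        out.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                age=float(row.get("age", float("nan"))),
                sex=str(row.get("sex", "M")),
                survival_days=float(row.get("survival_days", float("nan"))),
                event=bool(row.get("event", False)),
            )
        )
    return out


def case_mask(records: Sequence[SampleRecord]) -> np.ndarray:
    """Boolean case (HCC) indicator aligned with ``records``."""
    return np.array([r.is_case for r in records], dtype=bool)


def grades(records: Sequence[SampleRecord]) -> np.ndarray:
    return np.array([r.grade for r in records], dtype=int)
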