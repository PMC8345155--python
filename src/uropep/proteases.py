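"""Cleavage-site reconstruction, protease association and activity scoring.

Naturally occurring urinary peptides are footprints of endogenous
proteolysis: each peptide terminus marks a cleavage event whose local
context — four residues on either side of the scissile bond, written
P4 P3 P2 P1 | P1' P2' P3' P4' — can be reconstructed from the peptide's
terminal residues and the flanking regions of its parent protein.  Matching
these octamers against protease specificity rules associates candidate
proteases with each peptide; the per-patient *activity surrogate* of a
protease is then the arithmetic mean amplitude of its substrate peptides
(zeros included), and case/control fold changes of this surrogate indicate
altered proteolysis.

Sequence QC utilities: monoisotopic mass recomputation (hydroxyproline and
oxidized methionine as +15.99491 Da) and the charge/migration-time
consistency check (peptide charge at the CE operating pH of 2 is 1 for the
N-terminal amine plus one per K/R/H residue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import PeakMatrix, SampleRecord, SequenceAnnotation, case_mask

#: Mass shift of hydroxylation/oxidation (hydroxyproline, oxidized Met), Da.
OXIDATION_DA = 15.994915

_SITE_POSITIONS = ("P4", "P3", "P2", "P1", "P1p", "P2p", "P3p", "P4p")


@dataclass(frozen=True)
class CleavageSite:
    """One reconstructed cleavage site (N- or C-terminal) of a peptide.

    ``p_side`` holds P4..P1 (up to 4 residues left of the scissile bond,
    right-aligned), ``p_prime_side`` holds P1'..P4'.  ``exists`` is False at
    protein termini (empty flank), where no cleavage occurred.  Residues are
    upper-cased (modification-agnostic matching).
    """

    peptide_id: str
    terminus: str  # "N" or "C"
    p_side: str
    p_prime_side: str
    exists: bool

    @property
    def octamer(self) -> str:
        return f"{self.p_side}|{self.p_prime_side}"


def reconstruct_sites(annotations: Iterable[SequenceAnnotation]) -> list[CleavageSite]:
    """Two sites per peptide: the N-terminal site (P-side = protein flank,
    P'-side = first peptide residues) and the C-terminal site (P-side =
    last peptide residues, P'-side = protein flank)."""
    sites = []
    for ann in annotations:
        seq = ann.sequence.upper()
        n_flank = ann.n_flank.upper()
        c_flank = ann.c_flank.upper()
        sites.append(
            CleavageSite(
                peptide_id=ann.peptide_id,
                terminus="N",
                p_side=n_flank[-4:],
                p_prime_side=seq[:4],
                exists=bool(n_flank),
            )
        )
        sites.append(
            CleavageSite(
                peptide_id=ann.peptide_id,
                terminus="C",
                p_side=seq[-4:],
                p_prime_side=c_flank[:4],
                exists=bool(c_flank),
            )
        )
    return sites


@dataclass(frozen=True)
class ProteaseRule:
    """Positional specificity of one protease.

    ``allowed`` maps each of P4..P1, P1'..P4' (keys ``P4``..``P1``,
    ``P1p``..``P4p``) to the set of allowed residues; a missing key or the
    wildcard set ``None`` matches anything.  At least one position must be
    constrained.
    """

    protease: str
    allowed: Mapping[str, frozenset[str] | None]

    def __post_init__(self) -> None:
        if not any(v is not None for v in self.allowed.values()):
            raise ValueError(f"rule for {self.protease} is all-wildcard")
        bad = set(self.allowed) - set(_SITE_POSITIONS)
        if bad:
            raise ValueError(f"unknown site positions {sorted(bad)}")

    def matches(self, site: CleavageSite) -> bool:
        """True if every constrained position is satisfied by the site.

        Positions absent from a truncated site (short flank near a protein
        terminus) fail any non-wildcard constraint.  Sites with
        ``exists=False`` never match.
        """
        if not site.exists:
            return False
        # right-align P-side (P1 adjacent to the bond), left-align P'-side
        residues: dict[str, str] = {}
        for offset, pos in enumerate(("P1", "P2", "P3", "P4")):
            idx = len(site.p_side) - 1 - offset
            if idx >= 0:
                residues[pos] = site.p_side[idx]
        for offset, pos in enumerate(("P1p", "P2p", "P3p", "P4p")):
            if offset < len(site.p_prime_side):
                residues[pos] = site.p_prime_side[offset]
        for pos, allowed in self.allowed.items():
            if allowed is None:
                continue
            if residues.get(pos) not in allowed:
                return False
        return True


def parse_rules(frame: pd.DataFrame) -> list[ProteaseRule]:
    """Parse a rule table with columns ``protease`` and P4..P1, P1p..P4p,
    each cell an allowed-residue string or ``*`` (wildcard)."""
    rules = []
    for _, row in frame.iterrows():
        allowed: dict[str, frozenset[str] | None] = {}
        for pos in _SITE_POSITIONS:
            cell = str(row.get(pos, "*")).strip()
            allowed[pos] = None if cell in ("*", "", "nan") else frozenset(cell.upper())
        rules.append(ProteaseRule(protease=str(row["protease"]), allowed=allowed))
    return rules


def associate_proteases(
    sites: Sequence[CleavageSite], rules: Sequence[ProteaseRule]
) -> dict[str, set[str]]:
    """Protease -> substrate-peptide-id map.

    A peptide is a substrate of a protease if *any* existing site of the
    peptide matches *any* of the protease's rules; a peptide matching at
    both termini is counted once.
    """
    mapping: dict[str, set[str]] = {}
    for rule in rules:
        for site in sites:
            if rule.matches(site):
                mapping.setdefault(rule.protease, set()).add(site.peptide_id)
    return mapping


@dataclass
class ProteaseActivityTable:
    """Per-sample, per-protease activity surrogate (mean substrate amplitude,
    ion counts) plus the substrate map it was computed from."""

    activity: pd.DataFrame  # samples x proteases
    substrate_map: dict[str, set[str]]


def activity_scores(
    peaks: PeakMatrix, substrate_map: Mapping[str, Iterable[str]]
) -> ProteaseActivityTable:
    """activity(sample, protease) = arithmetic mean of the sample's
    amplitudes over the protease's substrate set, zeros included."""
    columns = {}
    for protease, substrates in substrate_map.items():
        substrates = sorted(set(map(str, substrates)))
        missing = [p for p in substrates if p not in peaks.amplitudes.columns]
        if missing:
            raise KeyError(
                f"substrate peptide(s) {missing} of {protease} absent from matrix"
            )
        columns[protease] = peaks.amplitudes[substrates].mean(axis=1)
    table = pd.DataFrame(columns, index=peaks.amplitudes.index)
    return ProteaseActivityTable(
        activity=table, substrate_map={k: set(map(str, v)) for k, v in substrate_map.items()}
    )


def fold_change_stats(
    table: ProteaseActivityTable, records: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Case/control fold change of each protease's activity surrogate.

    fold = mean(case activities) / mean(control activities); two-sided
    Mann–Whitney U p per protease, BH-adjusted across proteases.  Control =
    all non-case samples.  A zero control mean leaves the fold change NaN
    (flagged in the ``undefined`` column).
    """
    is_case = case_mask(records)
    if is_case.all() or not is_case.any():
        raise ValueError("need both case and control samples")
    act = table.activity
    rows = []
    for protease in act.columns:
        case_vals = act.loc[np.asarray(is_case), protease].to_numpy()
        ctrl_vals = act.loc[~np.asarray(is_case), protease].to_numpy()
        case_mean, ctrl_mean = case_vals.mean(), ctrl_vals.mean()
        undefined = ctrl_mean == 0
        fold = case_mean / ctrl_mean if not undefined else float("nan")
        if np.all(case_vals == case_vals[0]) and np.all(ctrl_vals == case_vals[0]):
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(case_vals, ctrl_vals, alternative="two-sided").pvalue
            )
        rows.append(
            {
                "protease": protease,
                "case_mean": case_mean,
                "case_sd": case_vals.std(ddof=1) if len(case_vals) > 1 else 0.0,
                "control_mean": ctrl_mean,
                "control_sd": ctrl_vals.std(ddof=1) if len(ctrl_vals) > 1 else 0.0,
                "fold_change": fold,
                "p": p,
                "undefined": undefined,
            }
        )
    out = pd.DataFrame(rows).set_index("protease", drop=False)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Sequence QC

_LEGAL = set("ACDEFGHIKLMNPQRSTVWY")


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic peptide mass in Da.

    Lowercase ``p`` (hydroxyproline) and ``m`` (oxidized methionine) add
    +15.994915 Da to the Pro/Met residue mass.
    """
    n_mod = sequence.count("p") + sequence.count("m")
    plain = sequence.upper()
    bad = set(plain) - _LEGAL
    if bad or not sequence:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {sequence!r}")
    return float(_pmass.fast_mass(plain)) + n_mod * OXIDATION_DA


def predicted_charge_ph2(sequence: str) -> int:
    """Peptide charge at pH 2: the protonated N-terminal amine plus one per
    basic residue (K, R, H)."""
    seq = sequence.upper()
    bad = set(seq) - _LEGAL
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {sequence!r}")
    return 1 + sum(seq.count(r) for r in "KRH")


def charge_time_consistency(
    annotations: Sequence[SequenceAnnotation],
    peptide_info: pd.DataFrame,
    resid_threshold: float = 3.0,
) -> list[str]:
    """Flag peptides whose CE migration time is inconsistent with their
    sequence-predicted charge.

    Regresses CE time on predicted charge and ln(mass) over all annotated
    peptides and flags those with absolute externally studentized residual
    above ``resid_threshold``.  Requires >= 5 annotated peptides present in
    ``peptide_info`` (index: peptide id, columns ``mass``, ``ce_time``).
    """
    import statsmodels.api as sm

    rows = []
    for ann in annotations:
        if ann.peptide_id not in peptide_info.index:
            continue
        rows.append(
            {
                "peptide_id": ann.peptide_id,
                "charge": predicted_charge_ph2(ann.sequence),
                "ln_mass": np.log(float(peptide_info.loc[ann.peptide_id, "mass"])),
                "ce_time": float(peptide_info.loc[ann.peptide_id, "ce_time"]),
            }
        )
    if len(rows) < 5:
        raise ValueError(f"need >= 5 annotated peptides, got {len(rows)}")
    frame = pd.DataFrame(rows)
    X = sm.add_constant(frame[["charge", "ln_mass"]].to_numpy())
    fit = sm.OLS(frame["ce_time"].to_numpy(), X).fit()
    resid = fit.get_influence().resid_studentized_external
    flagged = frame.loc[np.abs(resid) > resid_threshold, "peptide_id"]
    return list(flagged)
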