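import numpy as np
import pandas as pd
import pytest

import uropep as u
from conftest import make_peak_matrix
from uropep.types import SampleRecord, SequenceAnnotation

# independent residue-mass table (monoisotopic, Da) for the mass oracle
RESIDUE_DA = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_DA = 18.010565


def mass_oracle(seq):
    total = WATER_DA
    for ch in seq:
        total += RESIDUE_DA[ch.upper()] + (15.994915 if ch in "pm" else 0.0)
    return total


class TestCleavageSites:
    def test_interior_peptide_reconstruction(self):
        ann = SequenceAnnotation("1160", "UMOD", 592, 599, "VIDQSRVL", "RSGS", "NLGP")
        n_site, c_site = u.reconstruct_sites([ann])
        assert n_site.octamer == "RSGS|VIDQ" and n_site.exists
        assert c_site.octamer == "SRVL|NLGP" and c_site.exists

    def test_protein_terminal_site_does_not_exist(self):
        ann = SequenceAnnotation("5284", "HBB", 136, 147, "AGVANALAHKYH", "QKVV", "")
        _, c_site = u.reconstruct_sites([ann])
        assert not c_site.exists and c_site.p_prime_side == ""

    def test_short_flank_truncates_p_side(self):
        ann = SequenceAnnotation("x", "FOO", 3, 8, "ABCDEF".replace("B", "G"), "YW", "")
        n_site, _ = u.reconstruct_sites([ann])
        assert n_site.p_side == "YW" and n_site.p_prime_side == "AGCD"

    def test_modified_residues_uppercased_for_matching(self):
        ann = SequenceAnnotation("4829", "COL3A1", 179, 191, "pGPpGPpGTSGHp", "PAGP", "GSPG")
        n_site, c_site = u.reconstruct_sites([ann])
        assert n_site.p_prime_side == "PGPP"
        assert c_site.p_side == "SGHP"

    def test_bundled_panel_decomposition_matches_table(self):
        frame = u.load_fixture("table3").dropna(subset=["sequence"]).set_index("peptide_id")
        sites = {(s.peptide_id, s.terminus): s for s in u.reconstruct_sites(u.marker_annotations())}
        assert len(sites) == 54  # two per sequenced peptide
        for pid, row in frame.iterrows():
            seq = str(row["sequence"]).upper()
            n_flank = "" if pd.isna(row["n_flank"]) else str(row["n_flank"]).upper()
            c_flank = "" if pd.isna(row["c_flank"]) else str(row["c_flank"]).upper()
            n_site, c_site = sites[(pid, "N")], sites[(pid, "C")]
            assert n_site.p_side == n_flank[-4:] and n_site.p_prime_side == seq[:4]
            assert c_site.p_side == seq[-4:] and c_site.p_prime_side == c_flank[:4]
            assert n_site.exists == bool(n_flank) and c_site.exists == bool(c_flank)


class TestRuleMatching:
    def tryptic_rule(self):
        return u.ProteaseRule("TRYP_LIKE", {"P1": frozenset("KR")})

    def test_p1_rule_matches_basic_residue(self):
        ann = SequenceAnnotation("a", "FOO", 10, 14, "GLYSA", "TTLR", "MGGA")
        sites = u.reconstruct_sites([ann])
        assert self.tryptic_rule().matches(sites[0])      # ...TTLR | GLYS
        assert not self.tryptic_rule().matches(sites[1])  # LYSA | MGGA

    def test_truncated_position_fails_constraint(self):
        rule = u.ProteaseRule("X", {"P4": frozenset("T")})
        ann = SequenceAnnotation("a", "FOO", 10, 14, "GLYSA", "LR", "")
        sites = u.reconstruct_sites([ann])
        assert not rule.matches(sites[0])  # P4 absent in 2-residue flank

    def test_all_wildcard_rule_rejected(self):
        with pytest.raises(ValueError):
            u.ProteaseRule("X", {p: None for p in ("P1", "P2")})

    def test_association_deduplicates_double_matches(self):
        # K at both termini: peptide appears once in the substrate set
        ann = SequenceAnnotation("b", "FOO", 10, 13, "GASK", "TTLK", "MGGA")
        mapping = u.associate_proteases(u.reconstruct_sites([ann]), [self.tryptic_rule()])
        assert mapping == {"TRYP_LIKE": {"b"}}

    def test_empty_rule_list_gives_empty_map(self):
        sites = u.reconstruct_sites(u.marker_annotations())
        assert u.associate_proteases(sites, []) == {}

    def test_demo_rule_table_parses_and_matches_panel(self):
        rules = u.parse_rules(u.load_fixture("synthetic_demo_rules"))
        assert len(rules) == 4
        mapping = u.associate_proteases(u.reconstruct_sites(u.marker_annotations()), rules)
        # collagen fragments start with G sites frequently: XAA_GLY must hit
        assert len(mapping.get("XAA_GLY", set())) > 5


class TestCuratedAssociations:
    def test_klk6_substrate_set(self):
        mapping = u.marker_association_map()
        assert mapping["KLK6"] == {"1160", "4829", "6601", "13176"}

    def test_all_seven_proteases_present(self):
        mapping = u.marker_association_map()
        assert set(mapping) == {"MEP1A", "MMP3", "MMP13", "KLK6", "CTSB", "CTSD", "CTSE"}


class TestActivityScores:
    def test_simple_mean(self):
        amp = pd.DataFrame({"A": [2.0], "B": [4.0]}, index=["S1"])
        info = pd.DataFrame({"mass": [1000.0, 1100.0], "ce_time": [25.0, 26.0]},
                            index=["A", "B"])
        pm = u.PeakMatrix(amp, info)
        table = u.activity_scores(pm, {"PROT": {"A", "B"}})
        assert table.activity.loc["S1", "PROT"] == pytest.approx(3.0)

    def test_undetected_substrates_give_zero_activity(self):
        amp = pd.DataFrame({"A": [0.0], "B": [0.0]}, index=["S1"])
        info = pd.DataFrame({"mass": [1000.0, 1100.0], "ce_time": [25.0, 26.0]},
                            index=["A", "B"])
        table = u.activity_scores(u.PeakMatrix(amp, info), {"PROT": {"A", "B"}})
        assert table.activity.loc["S1", "PROT"] == 0.0

    def test_missing_substrate_rejected_by_name(self, small_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            u.activity_scores(small_matrix, {"PROT": {"NOPE"}})

    def test_linearity_identity_on_random_matrices(self, rng):
        # group mean of per-sample activities == mean over substrates of
        # per-group peptide means (exchange of the two averages)
        for _ in range(5):
            pm = make_peak_matrix(rng, n_samples=12, n_peptides=9)
            substrates = list(rng.choice(pm.peptide_ids, size=4, replace=False))
            table = u.activity_scores(pm, {"PROT": substrates})
            group = pm.sample_ids[:5]
            lhs = table.activity.loc[group, "PROT"].mean()
            rhs = pm.amplitudes.loc[group, substrates].mean(axis=0).mean()
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestFoldChanges:
    def records(self, n_case, n_ctrl):
        return (
            [SampleRecord(sample_id=f"C{i}", group="HCC") for i in range(n_case)]
            + [SampleRecord(sample_id=f"N{i}", group="LC") for i in range(n_ctrl)]
        )

    def table_from(self, case_vals, ctrl_vals):
        vals = list(case_vals) + list(ctrl_vals)
        ids = [f"C{i}" for i in range(len(case_vals))] + [f"N{i}" for i in range(len(ctrl_vals))]
        return u.ProteaseActivityTable(
            activity=pd.DataFrame({"PROT": vals}, index=ids), substrate_map={"PROT": {"x"}}
        )

    def test_small_worked_example(self):
        table = self.table_from([2.0, 4.0], [1.0, 1.0, 2.0])
        records = self.records(2, 3)
        out = u.fold_change_stats(table, records)
        assert out.loc["PROT", "fold_change"] == pytest.approx(2.25)

    def test_identical_groups(self):
        table = self.table_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = u.fold_change_stats(table, self.records(3, 3))
        assert out.loc["PROT", "fold_change"] == pytest.approx(1.0)
        assert out.loc["PROT", "p"] > 0.99

    def test_zero_control_mean_flagged(self):
        table = self.table_from([1.0, 2.0], [0.0, 0.0])
        out = u.fold_change_stats(table, self.records(2, 2))
        assert out.loc["PROT", "undefined"]
        assert np.isnan(out.loc["PROT", "fold_change"])

    def test_printed_group_means_reproduce_reported_directions(self):
        # reconstruct per-group substrate-mean activities from the bundled
        # marker table (weighting the 26 non-cirrhotic + 25 cirrhotic
        # controls) and compare the direction of each protease's fold change
        # with the bundled protease table
        t2 = u.load_fixture("table2").set_index("peptide_id")
        t4 = u.load_fixture("table4").set_index("protease")
        mapping = u.marker_association_map()
        for protease, subs in mapping.items():
            case = t2.loc[sorted(subs), "mean_hcc"].mean()
            ctrl = (
                26 * t2.loc[sorted(subs), "mean_nonlc"] + 25 * t2.loc[sorted(subs), "mean_lc"]
            ).div(51).mean()
            direction = case / ctrl > 1
            assert direction == (t4.loc[protease, "fold_change"] > 1), protease


class TestSequenceQC:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 75.0320), ("GPp", 285.1316), ("FNWVSR", 807.4028)],
    )
    def test_monoisotopic_mass_examples(self, seq, expected):
        assert u.monoisotopic_mass(seq) == pytest.approx(expected, abs=2e-3)

    def test_mass_matches_residue_sum_oracle(self):
        for ann in u.marker_annotations():
            assert u.monoisotopic_mass(ann.sequence) == pytest.approx(
                mass_oracle(ann.sequence), abs=1e-3
            )

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError):
            u.monoisotopic_mass("GXZ")

    @pytest.mark.parametrize(
        "seq,charge", [("VIDQSRVL", 2), ("AAAA", 1), ("KRH", 4)]
    )
    def test_predicted_charge_examples(self, seq, charge):
        assert u.predicted_charge_ph2(seq) == charge

    def test_collinear_charge_time_has_no_flags(self):
        anns, info = self._synthetic_annotations(outlier=False)
        assert u.charge_time_consistency(anns, info) == []

    def test_planted_charge_outlier_is_flagged(self):
        anns, info = self._synthetic_annotations(outlier=True)
        assert u.charge_time_consistency(anns, info) == ["pep08"]

    def test_too_few_points_rejected(self):
        anns, info = self._synthetic_annotations(outlier=False)
        with pytest.raises(ValueError):
            u.charge_time_consistency(anns[:3], info)

    @staticmethod
    def _synthetic_annotations(outlier):
        rng = np.random.default_rng(17)
        seqs = ["AAAA", "KAAA", "KRAA", "KRHA", "KAAAAA", "RRAA", "AAAAAA",
                "HAAA", "KKAA", "AAAR"]
        anns = []
        rows = {}
        for i, s in enumerate(seqs):
            pid = f"pep{i:02d}"
            anns.append(SequenceAnnotation(pid, "FOO", 1, len(s), s, "GGGG", "GGGG"))
            charge = u.predicted_charge_ph2(s)
            mass = 800.0 + 40 * i
            time = 20.0 - 2.5 * charge + 4.0 * np.log(mass) + rng.normal(0, 0.01)
            if outlier and pid == "pep08":
                time += 8.0
            rows[pid] = {"mass": mass, "ce_time": time}
        info = pd.DataFrame(rows).T
        return anns, info
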