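"""PTS grammar: set enumeration, scanning, and the candidate cascade."""
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgatlas import (
    ConfigError,
    EvidenceRow,
    ProteinRecord,
    PtsMotifConfig,
    call_peroxisomal_candidates,
    enumerate_pts1_set,
    scan_pts1,
    scan_pts2,
)

# brute-force derived: [SAP][KR][LM] expands to 12 tripeptides; AKM, PKM and
# PRM are excluded; SRI is added back as a literal -> 10 members
EXPECTED_PTS1_SET = {
    "SKL", "SKM", "SRL", "SRM", "AKL", "ARL", "ARM", "PKL", "PRL", "SRI",
}


def prot(seq, pid="p"):
    return ProteinRecord(pid, pid, seq)


class TestEnumeratePts1:
    def test_default_set(self, motif_config):
        result = enumerate_pts1_set(motif_config)
        assert result == EXPECTED_PTS1_SET
        assert len(result) == 10
        assert {"SKL", "SRI"} <= result
        assert not {"AKM", "PKM", "PRM"} & result

    def test_pure_function_of_config(self, motif_config):
        assert enumerate_pts1_set(motif_config) == enumerate_pts1_set(PtsMotifConfig())

    def test_excluded_must_be_subset_of_pattern(self):
        with pytest.raises(ConfigError):
            PtsMotifConfig(pts1_excluded=frozenset({"WWW"}))


class TestScanPts1:
    @pytest.mark.parametrize(
        "seq, expect_motif, expect_pos",
        [
            ("MAGVSKL", "SKL", 5),     # canonical terminal signal
            ("MAGVSRI", "SRI", 5),     # literal extra
            ("MAGVPRM", None, None),   # excluded tripeptide
            ("SKLMAGV", None, None),   # internal motif does not count
            ("MA", None, None),        # too short for a tripeptide
        ],
    )
    def test_examples(self, motif_config, seq, expect_motif, expect_pos):
        match = scan_pts1(prot(seq), motif_config)
        if expect_motif is None:
            assert match is None
        else:
            assert (match.motif, match.position) == (expect_motif, expect_pos)
            assert match.position == len(seq) - 2


class TestScanPts2:
    def test_simple_match(self, motif_config):
        (m,) = scan_pts2(prot("MARLQQQQQHLGG"), motif_config)
        assert (m.motif, m.position) == ("RLQQQQQHL", 3)

    def test_window_excludes_deep_motifs(self, motif_config):
        seq = "G" * 60 + "RLQQQQQHL" + "G" * 10
        assert scan_pts2(prot(seq), motif_config) == []
        wide = PtsMotifConfig(pts2_window=80)
        assert len(scan_pts2(prot(seq), wide)) == 1

    def test_span_must_fit_entirely_in_window(self, motif_config):
        # starts at residue 33: span runs 33..41, past the 40-residue window
        seq = "G" * 32 + "RLQQQQQHL" + "G" * 30
        assert scan_pts2(prot(seq), motif_config) == []

    def test_liv_variant_config_switch(self, motif_config):
        seq = "MARVQQQQQHL"
        assert scan_pts2(prot(seq), motif_config) == []
        liv = motif_config.with_pts2_variant("LIV")
        (m,) = scan_pts2(prot(seq), liv)
        assert m.motif == "RVQQQQQHL"

    def test_ambiguous_residues_never_satisfy_classes(self, motif_config):
        assert scan_pts2(prot("MARXQQQQQHL"), motif_config) == []
        assert scan_pts1(prot("MAGVSKX"), motif_config) is None


# ---------------------------------------------------------------------------
# oracle equivalence & properties
# ---------------------------------------------------------------------------

def regex_oracles(config):
    """Independent regular-expression oracles built directly from the config."""
    tris = sorted(
        {a + b + c
         for a in config.pts1_position1
         for b in config.pts1_position2
         for c in config.pts1_position3}
        - set(config.pts1_excluded) | set(config.pts1_extra)
    )
    pts1_re = re.compile("(?:" + "|".join(tris) + r")\Z")
    cls = "".join(sorted(config.pts2_position2_class))
    pts2_re = re.compile(rf"(?=(R[{cls}][A-Z]{{5}}HL))")
    return pts1_re, pts2_re


def oracle_scan(seq, config):
    pts1_re, pts2_re = regex_oracles(config)
    pts1 = bool(pts1_re.search(seq))
    pts2 = [
        m.start() + 1
        for m in pts2_re.finditer(seq)
        if m.start() + 9 <= config.pts2_window
    ]
    return pts1, pts2


AA = "ACDEFGHIKLMNPQRSTVWY"


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet=AA + "XR" + "HL" + "SKL", min_size=3, max_size=80))
def test_scanners_agree_with_regex_oracle(seq):
    config = PtsMotifConfig()
    p = prot(seq)
    pts1, pts2_positions = oracle_scan(seq, config)
    assert (scan_pts1(p, config) is not None) == pts1
    assert [m.position for m in scan_pts2(p, config)] == pts2_positions


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet=AA, min_size=9, max_size=80),
       st.integers(min_value=9, max_value=60))
def test_pts2_monotone_in_window_and_class(seq, window):
    """Enlarging the window or the second-position class never loses a match."""
    p = prot(seq)
    narrow = PtsMotifConfig(pts2_window=window)
    wider = PtsMotifConfig(pts2_window=window + 10)
    liv = PtsMotifConfig(pts2_window=window, pts2_position2_class=frozenset("LIV"))
    base = {m.position for m in scan_pts2(p, narrow)}
    assert base <= {m.position for m in scan_pts2(p, wider)}
    assert base <= {m.position for m in scan_pts2(p, liv)}


def test_exclusion_soundness_on_random_decoys():
    rng = np.random.default_rng(7)
    letters = np.array(list(AA))
    config = PtsMotifConfig()
    for i in range(300):
        body = "".join(letters[rng.integers(0, 20, size=30)])
        tri = ("AKM", "PKM", "PRM")[i % 3]
        assert scan_pts1(prot(body + tri), config) is None


# ---------------------------------------------------------------------------
# candidate cascade
# ---------------------------------------------------------------------------

def tm_row(pid, helices):
    return EvidenceRow(pid, "tmhmm", "default",
                       "membrane" if helices else "other", float(helices))


def pred_row(pid, positive):
    return EvidenceRow(pid, "pts1predictor", "GENERAL",
                       "peroxisomal" if positive else "other")


class TestCallPeroxisomalCandidates:
    PROTEINS = [
        prot("M" * 30 + "VSKL", "gdh"),       # motif only, soluble
        prot("M" * 30 + "VSKL", "memb"),      # motif but 2 TM helices
        prot("M" * 30 + "VGGG", "predonly"),  # predictor only
        prot("M" * 30 + "VSKL", "both"),      # motif + predictor agree
        prot("M" * 30 + "VGGG", "nothing"),   # no channel at all
    ]
    TM = [tm_row("memb", 2), tm_row("gdh", 0)]
    PRED = [pred_row("predonly", True), pred_row("both", True),
            pred_row("gdh", False)]

    def calls(self):
        out = call_peroxisomal_candidates(self.PROTEINS, self.TM, self.PRED)
        return {c.protein_id: c for c in out}

    def test_motif_only_is_weak_candidate(self):
        # a terminal SKL alone qualifies even when the external predictor
        # does not support it
        call = self.calls()["gdh"]
        assert call.tier == "weak"
        assert call.evidence["pts1"] == "SKL"

    def test_tm_proteins_are_filtered_out(self):
        assert self.calls()["memb"].tier == "excluded"

    def test_predictor_only_is_weak_candidate(self):
        assert self.calls()["predonly"].tier == "weak"

    def test_motif_and_predictor_agree_is_strong(self):
        assert self.calls()["both"].tier == "strong"

    def test_silent_proteins_are_omitted(self):
        assert "nothing" not in self.calls()

    def test_unknown_tm_protein_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="orgatlas"):
            call_peroxisomal_candidates(self.PROTEINS, [tm_row("ghost", 1)], [])
        assert "ghost" in caplog.text
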