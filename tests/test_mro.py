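"""NTS consensus rule and three-line evidence fusion for the MRO proteome."""
import random

import pytest

from orgatlas import (
    ConsensusRuleConfig,
    EvidenceRow,
    ExperimentalEvidence,
    HomologyEvidence,
    InvariantError,
    integrate_mro_evidence,
    nts_consensus,
)


def row(pid, tool, setting="default", label="mitochondrial"):
    return EvidenceRow(pid, tool, setting, label)


class TestNtsConsensus:
    def test_single_deciding_setting_suffices(self):
        verdicts = nts_consensus([row("p1", "multiloc2", "animal")])
        assert verdicts["p1"].positive
        assert verdicts["p1"].contributing == (("multiloc2", "animal"),)

    def test_supporting_tools_never_flip_the_verdict(self):
        verdicts = nts_consensus([
            row("p1", "targetp2", "non-plant"),
            row("p1", "multiloc2", "animal", label="cytosolic"),
            row("p1", "nommpred", "MRO", label="other"),
        ])
        assert not verdicts["p1"].positive
        assert verdicts["p1"].supporting == (("targetp2", "non-plant"),)

    def test_no_positive_tool_is_negative(self):
        verdicts = nts_consensus([row("p1", "multiloc2", "animal", label="other")])
        assert not verdicts["p1"].positive

    def test_plant_settings_are_omitted_by_default(self):
        rows = [row("p1", "multiloc2", "plant")]
        assert not nts_consensus(rows)["p1"].positive
        keep = ConsensusRuleConfig(omit_plant_settings=False)
        assert nts_consensus(rows, keep)["p1"].positive

    def test_unscored_proteins_default_negative(self):
        verdicts = nts_consensus([], protein_ids=["lonely"])
        assert not verdicts["lonely"].positive
        assert verdicts["lonely"].unscored

    def test_disjointness_enforced(self):
        with pytest.raises(Exception):
            ConsensusRuleConfig(deciding_tools=frozenset({"multiloc2"}),
                                supporting_tools=frozenset({"multiloc2"}))


# ---------------------------------------------------------------------------
# evidence fusion
# ---------------------------------------------------------------------------

def homology(pid, subject="Mb_prot_77", refset="Mb_hydrogenosome"):
    return HomologyEvidence(pid, refset, subject, 1e-40, 250.0)


def verdicts_for(pid, n_deciding):
    settings = [("multiloc2", "animal"), ("nommpred", "MRO")][:n_deciding]
    rows = [row(pid, t, s) for t, s in settings]
    rows.append(row(pid, "multiloc2", "fungal", label="other"))
    return nts_consensus(rows)


# hand-written decision table over all channel combinations:
#   hom: none | ordinary | hallmark      (homology line)
#   nts: 0, 1 or 2 positive deciding (tool, setting) pairs
#   exp: absent | mito | nonmito         (curated yeast localization)
# Rules: hallmark -> strong always; a curated non-mitochondrial result plus a
# lone single-tool NTS call and no homology -> excluded; otherwise count
# positive channels (homology, NTS, experimental-mito): >=2 strong, 1 weak,
# 0 excluded.
DECISION_TABLE = [
    # hom,       nts, exp,       expected tier
    ("none",     0,   "absent",  "excluded"),
    ("none",     0,   "mito",    "weak"),
    ("none",     0,   "nonmito", "excluded"),
    ("none",     1,   "absent",  "weak"),
    ("none",     1,   "mito",    "strong"),
    ("none",     1,   "nonmito", "excluded"),  # the ACL pattern
    ("none",     2,   "absent",  "weak"),
    ("none",     2,   "mito",    "strong"),
    ("none",     2,   "nonmito", "weak"),
    ("ordinary", 0,   "absent",  "weak"),
    ("ordinary", 0,   "mito",    "strong"),
    ("ordinary", 0,   "nonmito", "weak"),
    ("ordinary", 1,   "absent",  "strong"),
    ("ordinary", 1,   "mito",    "strong"),
    ("ordinary", 1,   "nonmito", "strong"),
    ("ordinary", 2,   "absent",  "strong"),
    ("ordinary", 2,   "mito",    "strong"),
    ("ordinary", 2,   "nonmito", "strong"),
] + [
    ("hallmark", n, e, "strong")
    for n in (0, 1, 2) for e in ("absent", "mito", "nonmito")
]


class TestIntegrateMroEvidence:
    @pytest.mark.parametrize("hom, nts, exp, expected", DECISION_TABLE)
    def test_decision_table(self, hom, nts, exp, expected):
        pid = "p1"
        verdicts = verdicts_for(pid, nts)
        hom_rows = {
            "none": [],
            "ordinary": [homology(pid)],
            "hallmark": [homology(pid, subject="Tom40")],
        }[hom]
        exp_rows = {
            "absent": [],
            "mito": [ExperimentalEvidence(pid, "mitochondrial")],
            "nonmito": [ExperimentalEvidence(pid, "vesicular")],
        }[exp]
        (call,) = integrate_mro_evidence(verdicts, hom_rows, exp_rows)
        assert call.tier == expected, (hom, nts, exp)

    def test_acl_case_single_tool_plus_nonmito_yeast_excluded(self):
        # weak single-tool NTS call, no homology, vesicular in yeast
        (call,) = integrate_mro_evidence(
            verdicts_for("ACL", 1), [], [ExperimentalEvidence("ACL", "vesicular")]
        )
        assert call.tier == "excluded"

    def test_cpn10_case_hallmark_survives_failed_yeast_localization(self):
        (call,) = integrate_mro_evidence(
            verdicts_for("cpn10", 1),
            [homology("cpn10", subject="cpn10")],
            [ExperimentalEvidence("cpn10", "cytosolic")],
        )
        assert call.tier == "strong"
        assert call.evidence["hallmark"] == "yes"

    def test_p5cr_case_excluded_with_pts_is_reassigned_to_peroxisome(self):
        (call,) = integrate_mro_evidence(
            verdicts_for("P5CR", 1),
            [],
            [ExperimentalEvidence("P5CR", "cytosolic")],
            pts_positive={"P5CR"},
        )
        assert call.tier == "excluded"
        assert call.evidence["reassignment"] == "peroxisome"

    def test_conflicting_experimental_rows_hard_error(self):
        with pytest.raises(InvariantError, match="conflicting"):
            integrate_mro_evidence(
                {}, [],
                [ExperimentalEvidence("p1", "mitochondrial"),
                 ExperimentalEvidence("p1", "cytosolic")],
            )

    def test_determinism_under_input_order(self):
        rows = [row(f"p{i}", "multiloc2", "animal") for i in range(10)]
        homs = [homology(f"p{i}") for i in range(0, 10, 2)]
        exps = [ExperimentalEvidence(f"p{i}", "mitochondrial") for i in (1, 3)]
        baseline = integrate_mro_evidence(nts_consensus(rows), homs, exps)
        rng = random.Random(5)
        for _ in range(5):
            rng.shuffle(rows), rng.shuffle(homs), rng.shuffle(exps)
            assert integrate_mro_evidence(nts_consensus(rows), homs, exps) == baseline

    def test_adding_deciding_positive_never_demotes(self):
        """Monotonicity absent overrides: an extra deciding-tool positive
        can only hold or raise the tier."""
        order = {"excluded": 0, "weak": 1, "strong": 2}
        for hom in ([], [homology("p1")]):
            for exp in ([], [ExperimentalEvidence("p1", "mitochondrial")]):
                (before,) = integrate_mro_evidence(verdicts_for("p1", 0), hom, exp)
                (after,) = integrate_mro_evidence(verdicts_for("p1", 1), hom, exp)
                assert order[after.tier] >= order[before.tier]
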