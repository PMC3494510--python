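import numpy as np
import pytest

from xenoscreen.alien_screen import AlienScore
from xenoscreen.errors import DataError
from xenoscreen.hgt_calls import (
    PipelineConfig,
    classify_gene,
    cluster_families,
    monophyly_test,
    shared_architecture_test,
)
from xenoscreen.io_formats import DomainAnnotation, TaxonomyMap
from xenoscreen.trees import SupportTree

from oracles import brute_force_monophyly, random_tree_newick, union_find_components


class TestMonophyly:
    def test_clean_pass(self):
        t = SupportTree.from_newick(
            "(((r1:1,r2:1)90:1,(d1:1,d2:1)88:1)85:1,o1:1,o2:1);"
        )
        mc = monophyly_test(t, ["r1", "r2"], ["d1", "d2"], 70)
        assert mc.verdict == "pass"
        assert mc.clade_members == frozenset({"r1", "r2", "d1", "d2"})
        assert mc.clade_support == 85

    def test_interleaved_fail(self):
        t = SupportTree.from_newick("((r1:1,o1:1)99:1,(r2:1,d1:1)99:1,d2:1);")
        mc = monophyly_test(t, ["r1", "r2"], ["d1", "d2"], 70)
        assert mc.verdict == "fail"

    def test_uninformative_without_outgroup(self):
        t = SupportTree.from_newick("((r1:1,r2:1)90:1,d1:1,d2:1);")
        mc = monophyly_test(t, ["r1", "r2"], ["d1", "d2"], 70)
        assert mc.verdict == "uninformative" and not mc.informative

    def test_low_support_is_fail_with_clade_reported(self):
        t = SupportTree.from_newick(
            "(((r1:1,r2:1)90:1,(d1:1,d2:1)88:1)60:1,o1:1,o2:1);"
        )
        mc = monophyly_test(t, ["r1", "r2"], ["d1", "d2"], 70)
        assert mc.verdict == "fail"
        assert mc.clade_support == 60
        assert mc.clade_members == frozenset({"r1", "r2", "d1", "d2"})

    def test_support_exactly_70_passes(self):
        t = SupportTree.from_newick(
            "(((r1:1,r2:1)90:1,d1:1)70:1,o1:1,o2:1);"
        )
        mc = monophyly_test(t, ["r1", "r2"], ["d1"], 70)
        assert mc.verdict == "pass" and mc.clade_support == 70

    def test_tautological_complement_is_not_evidence(self):
        # {r1,d1,d2} is the complement of the lone outside leaf o1; that split
        # exists in every tree on these leaves, so it must not grant a pass
        t = SupportTree.from_newick("((r1:1,d1:1)55:1,d2:1,o1:1);")
        mc = monophyly_test(t, ["r1"], ["d1", "d2"], 70)
        assert mc.verdict == "fail"
        # the real evidence, the {r1,d1} split, is reported with its support
        assert mc.clade_members == frozenset({"r1", "d1"})
        assert mc.clade_support == 55

    def test_two_outside_leaves_clade_passes(self):
        t = SupportTree.from_newick("(((r1:1,r2:1)90:1,(d1:1,d2:1)88:1)85:1,o1:1,o2:1);")
        mc = monophyly_test(t, ["r1", "r2"], ["d1", "d2"], 70)
        assert mc.verdict == "pass" and mc.clade_support == 85

    def test_smallest_qualifying_clade_reported(self):
        t = SupportTree.from_newick(
            "((((r1:1,r2:1)99:1,d1:1)95:1,d2:1)90:1,o1:1,o2:1);"
        )
        mc = monophyly_test(t, ["r1", "r2"], ["d1", "d2"], 70)
        assert mc.clade_members == frozenset({"r1", "r2", "d1"})
        assert mc.clade_support == 95

    def test_missing_recipient_errors(self):
        t = SupportTree.from_newick("((r1:1,d1:1)90:1,o1:1,o2:1);")
        with pytest.raises(DataError, match="r9"):
            monophyly_test(t, ["r1", "r9"], ["d1"], 70)

    def test_raising_threshold_never_converts_fail_to_pass(self):
        t = SupportTree.from_newick(
            "(((r1:1,r2:1)90:1,(d1:1,d2:1)88:1)72:1,o1:1,o2:1);"
        )
        verdicts = [
            monophyly_test(t, ["r1", "r2"], ["d1", "d2"], s).verdict
            for s in (0, 50, 72, 73, 100)
        ]
        # once fail, never pass again as s* rises
        assert "".join("P" if v == "pass" else "F" for v in verdicts) == "PPPFF"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        """Random trees + random group labelings agree with the brute-force oracle."""
        rng = np.random.default_rng(seed)
        for rep in range(25):
            n = int(rng.integers(4, 13))
            labels = [f"x{i}" for i in range(n)]
            nwk = random_tree_newick(labels, rng)
            t = SupportTree.from_newick(nwk)
            # attach random supports to internal splits
            supports = {
                s.side: int(rng.integers(0, 101)) for s in t.splits()
            }
            t.set_split_supports(supports)
            roles = rng.choice(["r", "d", "o"], size=n, p=[0.4, 0.4, 0.2])
            recipients = [l for l, ro in zip(labels, roles) if ro == "r"]
            donors = [l for l, ro in zip(labels, roles) if ro == "d"]
            if not recipients:
                continue
            got = monophyly_test(t, recipients, donors, 70).verdict
            want = brute_force_monophyly(t, recipients, donors, 70)
            assert got == want, f"seed={seed} rep={rep} nwk={nwk}"


class TestClusterFamilies:
    def test_single_linkage_chain(self):
        idents = {("r1", "r2"): 45.0, ("r2", "r3"): 35.0, ("r1", "r3"): 25.0}

        def fn(a, b):
            return idents[tuple(sorted((a, b)))]

        fams = cluster_families(["r1", "r2", "r3"], fn, link=0.30)
        assert len(fams) == 1
        assert fams[0].members == ["r1", "r2", "r3"]
        assert fams[0].identity_min == 25.0 and fams[0].identity_max == 45.0

    def test_low_identity_singletons(self):
        fams = cluster_families(["a", "b"], lambda x, y: 20.0, link=0.30)
        assert [f.members for f in fams] == [["a"], ["b"]]
        assert fams[0].identity_min is None

    def test_empty_input(self):
        assert cluster_families([], lambda a, b: 0.0) == []

    def test_matches_union_find_oracle(self, rng):
        ids = [f"q{i}" for i in range(12)]
        ident = {}
        for i in range(12):
            for j in range(i + 1, 12):
                ident[tuple(sorted((ids[i], ids[j])))] = float(rng.uniform(0, 60))

        def fn(a, b):
            return ident[tuple(sorted((a, b)))]

        fams = cluster_families(ids, fn, link=0.30)
        edges = [k for k, v in ident.items() if v >= 30.0]
        want = union_find_components(ids, edges)
        got = sorted(frozenset(f.members) for f in fams)
        assert got == want

    def test_raising_link_never_merges_more(self, rng):
        ids = [f"q{i}" for i in range(8)]
        ident = {}
        for i in range(8):
            for j in range(i + 1, 8):
                ident[(ids[i], ids[j])] = float(rng.uniform(0, 60))

        def fn(a, b):
            return ident[tuple(sorted((a, b)))]

        sizes = [len(cluster_families(ids, fn, link=l)) for l in (0.1, 0.3, 0.5)]
        assert sizes == sorted(sizes)


TAX = TaxonomyMap(
    {
        "algae": {"role": "donor", "patterns": ["alga"]},
        "animals": {"role": "recipient", "patterns": ["anim"]},
        "fungi": {"role": "close_relative", "patterns": ["fung"]},
        "protists": {"role": "other_eukaryote", "patterns": ["euk"]},
    }
)

ARCH = [
    DomainAnnotation("anim1", "IonTransN", 1, 50),
    DomainAnnotation("anim1", "IonTrans", 60, 150),
    DomainAnnotation("anim1", "cNMP", 160, 220),
    DomainAnnotation("alga1", "IonTransN", 5, 55),
    DomainAnnotation("alga1", "IonTrans", 70, 160),
    DomainAnnotation("alga1", "cNMP", 170, 230),
]


class TestArchitecture:
    def test_donor_exclusive_true(self):
        assert shared_architecture_test(ARCH, TAX, "anim1") is True

    def test_fungal_match_breaks_exclusivity(self):
        annos = ARCH + [
            DomainAnnotation("fung1", "IonTransN", 1, 50),
            DomainAnnotation("fung1", "IonTrans", 60, 150),
            DomainAnnotation("fung1", "cNMP", 160, 220),
        ]
        assert shared_architecture_test(annos, TAX, "anim1") is False

    def test_no_annotations_none(self):
        assert shared_architecture_test(None, TAX, "anim1") is None
        assert shared_architecture_test([], TAX, "anim1") is None
        assert shared_architecture_test(ARCH, TAX, "anim_unannotated") is None

    def test_order_matters(self):
        scrambled = [
            DomainAnnotation("alga2", "cNMP", 1, 60),
            DomainAnnotation("alga2", "IonTrans", 70, 150),
            DomainAnnotation("alga2", "IonTransN", 160, 220),
        ]
        # only the scrambled donor exists: architectures differ as sequences
        annos = [a for a in ARCH if a.seq_id == "anim1"] + scrambled
        assert shared_architecture_test(annos, TAX, "anim1") is False


def _alien(query_id="q", donor=100.0, nondonor=50.0, donor_only=False, candidate=True):
    ratio = None if donor is None or nondonor is None else donor / nondonor
    return AlienScore(query_id, donor, nondonor, ratio, donor_only, candidate)


def _mono(verdict):
    from xenoscreen.hgt_calls import MonophylyCall

    return MonophylyCall("q", frozenset({"q", "d"}), 90, verdict != "uninformative", verdict)


class TestClassify:
    def test_rule_table(self):
        assert classify_gene(_alien(), _mono("pass")).category == "algal_phylogenetic"
        assert (
            classify_gene(_alien(nondonor=None, donor_only=True), _mono("uninformative")).category
            == "algal_distribution_only"
        )
        assert (
            classify_gene(_alien(nondonor=None, donor_only=True), None).category
            == "algal_distribution_only"
        )
        assert classify_gene(_alien(), _mono("fail")).category == "candidate_unresolved"
        assert classify_gene(_alien(), None).category == "candidate_unresolved"
        assert (
            classify_gene(_alien(donor=60.0, nondonor=55.0, candidate=False), None).category
            == "rejected"
        )

    def test_architecture_never_promotes(self):
        call = classify_gene(_alien(), _mono("fail"), architecture=True)
        assert call.category == "candidate_unresolved"
        assert call.architecture_shared is True

    def test_every_query_gets_exactly_one_category(self):
        from xenoscreen.hgt_calls import CATEGORIES

        for donor_only in (False, True):
            for mono in (None, _mono("pass"), _mono("fail"), _mono("uninformative")):
                alien = _alien(
                    nondonor=None if donor_only else 50.0,
                    donor_only=donor_only,
                    candidate=True,
                )
                assert classify_gene(alien, mono).category in CATEGORIES


class TestPipelineConfig:
    def test_validation(self):
        with pytest.raises(DataError):
            PipelineConfig(tau_ratio=0)
        with pytest.raises(DataError):
            PipelineConfig(support_min=150)
        with pytest.raises(DataError):
            PipelineConfig(identity_link=1.5)
        with pytest.raises(DataError):
            PipelineConfig(n_boot=0)
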