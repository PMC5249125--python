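import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeaudit import (
    GradingError,
    OtuCluster,
    ReferenceMatch,
    assign_grade,
    bootstrap_supports,
    distance_matrix,
    flag_misidentifications,
    misid_report,
    nj_tree,
    review_otu,
    rsl_cluster,
    species_cohesion,
    species_summaries,
    sub_cluster_split,
)
from barcodeaudit.audit import is_interim_name
from barcodeaudit.distance import SpeciesDistanceSummary
from barcodeaudit.simulate import SimulationConfig, simulate_library

from conftest import make_library


class TestMisidentification:
    def test_injected_swaps_recovered_exactly(self):
        lib, truth = simulate_library(
            SimulationConfig(
                seed=21,
                n_species=4,
                n_specimens=15,
                misid_rate=0.1,
                misid_pairs=[(0, 1), (2, 3)],
            )
        )
        injected = set(truth.injected_misids().specimen_id)
        assert injected, "scenario must inject at least one swap"
        m = distance_matrix(lib)
        labels = lib.labels()
        otus = rsl_cluster(m)
        calls = flag_misidentifications(otus, m, labels, lib.divisions())
        called = {c.specimen_id for c in calls}
        assert called == injected
        truth_by_id = truth.specimens.set_index("specimen_id")
        for c in calls:
            assert c.barcode_label == truth_by_id.loc[c.specimen_id, "true_species"]

    def test_clean_library_produces_zero_calls(self):
        lib, _ = simulate_library(
            SimulationConfig(seed=22, n_species=4, n_specimens=10)
        )
        m = distance_matrix(lib)
        calls = flag_misidentifications(rsl_cluster(m), m, lib.labels())
        assert calls == []

    def test_report_groups_by_division_with_totals(self):
        lib, truth = simulate_library(
            SimulationConfig(
                seed=23, n_species=2, n_specimens=20, misid_rate=0.15
            )
        )
        m = distance_matrix(lib)
        labels, divisions = lib.labels(), lib.divisions()
        calls = flag_misidentifications(rsl_cluster(m), m, labels, divisions)
        df = misid_report(calls, labels, divisions)
        assert df.n_misid.sum() == len(calls)
        # every denominator counts the field-label carriers in that division
        for _, row in df.iterrows():
            expected = sum(
                1
                for sid, sp in labels.items()
                if sp == row.morph_label and divisions[sid] == row.division
            )
            assert row.n_total == expected


class TestInterimNames:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Mustelus sp.", True),
            ("Mustelus sp", True),
            ("Mustelus sp. zpl 00058", True),
            ("Torpedo sp. A", True),
            ("Dipturus oxyrinchus sp1", True),
            ("Raja clavata", False),
            ("Squalus acanthias", False),
            ("Scyliorhinus species-like", False),
        ],
    )
    def test_grammar(self, label, expected):
        assert is_interim_name(label) is expected


class TestReviewOtu:
    def test_interim_name_folds_into_single_congener(self):
        members = [f"S{i}" for i in range(75)]
        labels = {m: "Mustelus mustelus" for m in members[:72]}
        labels.update({m: "Mustelus sp." for m in members[72:]})
        r = review_otu(OtuCluster("O1", members), labels)
        assert r.post_review_status == "concordant"
        assert r.reasons == ["interim_name"]
        assert r.canonical_species == "Mustelus mustelus"

    def test_one_or_two_minority_records_reviewed_concordant(self):
        members = [f"S{i}" for i in range(108)]
        labels = {m: "Raja clavata" for m in members[:107]}
        labels[members[107]] = "Raja undulata"
        r = review_otu(OtuCluster("O1", members), labels)
        assert r.post_review_status == "concordant"
        assert "minority_misid" in r.reasons
        assert r.suspected_misids == [members[107]]

    def test_balanced_mixture_stays_discordant(self):
        members = [f"S{i}" for i in range(10)]
        labels = {m: "Dasyatis tortonesei" for m in members[:6]}
        labels.update({m: "Dasyatis pastinaca" for m in members[6:]})
        r = review_otu(OtuCluster("O1", members), labels)
        assert r.post_review_status == "discordant"
        assert r.reasons == ["multi_species"]

    def test_interim_fold_ambiguous_with_two_congeners(self):
        labels = {
            "S1": "Mustelus mustelus",
            "S2": "Mustelus punctulatus",
            "S3": "Mustelus sp.",
            "S4": "Mustelus mustelus",
            "S5": "Mustelus mustelus",
            "S6": "Mustelus punctulatus",
            "S7": "Mustelus punctulatus",
        }
        r = review_otu(OtuCluster("O1", list(labels)), labels)
        # cannot fold; three labels, minority too large -> discordant
        assert r.post_review_status == "discordant"

    @settings(max_examples=50, deadline=None)
    @given(extra=st.integers(min_value=0, max_value=50))
    def test_monotone_adding_conspecifics_keeps_concordance(self, extra):
        members = [f"S{i}" for i in range(5 + extra)]
        labels = {m: "Raja clavata" for m in members}
        labels[members[0]] = "Raja undulata"
        r = review_otu(OtuCluster("O1", members), labels)
        assert r.post_review_status == "concordant"


def summary(species, n, mean_i, max_i, nn_d):
    return SpeciesDistanceSummary(
        species=species,
        n=n,
        mean_intra=mean_i,
        max_intra=max_i,
        nn_species="Other species",
        nn_distance=nn_d,
        gap_present=None if max_i is None else max_i < nn_d,
    )


class TestGrading:
    def test_reference_match_to_self_cohesive_low_divergence_is_a(self):
        g = assign_grade(
            "Raja clavata",
            summary("Raja clavata", 5, 0.002, 0.004, 0.025),
            {"cohesive": True, "support": 99.0},
            ReferenceMatch("Raja clavata", True, "Raja clavata", 0.004),
        )
        assert g.grade == "A"

    def test_reference_match_to_other_species_is_e(self):
        g = assign_grade(
            "Squalus acanthias",
            summary("Squalus acanthias", 10, 0.001, 0.011, 0.068),
            {"cohesive": True},
            ReferenceMatch("Squalus acanthias", True, "Squalus suckleyi", 0.01),
        )
        assert g.grade == "E"

    def test_non_monophyletic_reference_match_is_e(self):
        g = assign_grade(
            "Dasyatis pastinaca",
            summary("Dasyatis pastinaca", 10, 0.03, 0.087, 0.079),
            {"cohesive": False},
            ReferenceMatch("Dasyatis pastinaca", True, "Dasyatis pastinaca", 0.01),
        )
        assert g.grade == "E"

    def test_reference_match_above_two_percent_is_c(self):
        g = assign_grade(
            "Genus alpha",
            summary("Genus alpha", 5, 0.01, 0.015, 0.05),
            {"cohesive": True},
            ReferenceMatch("Genus alpha", True, "Genus alpha", 0.031),
        )
        assert g.grade == "C"

    def test_internal_concordance_without_reference_is_b(self):
        g = assign_grade(
            "Genus alpha",
            summary("Genus alpha", 4, 0.002, 0.008, 0.06),
            {"cohesive": True},
            None,
        )
        assert g.grade == "B"

    def test_deep_intraspecific_divergence_is_c(self):
        g = assign_grade(
            "Genus alpha",
            summary("Genus alpha", 6, 0.015, 0.031, 0.06),
            {"cohesive": True},
            None,
        )
        assert g.grade == "C"

    def test_one_or_two_specimens_without_reference_is_d(self):
        g = assign_grade(
            "Mobula mobular",
            summary("Mobula mobular", 1, None, None, 0.16),
            {"cohesive": True},
            None,
        )
        assert g.grade == "D"

    def test_unresolvable_inputs_raise_instead_of_silently_grading(self):
        with pytest.raises(GradingError):
            assign_grade(
                "Genus alpha",
                summary("Genus alpha", 6, 0.01, 0.03, 0.02),
                {"cohesive": False},
                None,
            )

    def test_every_grade_comes_with_a_rationale(self):
        g = assign_grade(
            "Genus alpha",
            summary("Genus alpha", 4, 0.002, 0.008, 0.06),
            {"cohesive": True},
            None,
        )
        assert g.rationale


def _flip(seq, positions):
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = flip[out[p]]
    return "".join(out)


class TestSubClusterSplit:
    @pytest.fixture
    def interleaved_library(self):
        """'Genus alpha' consists of two lineages 24 substitutions apart,
        each sister to a *different* species, so the single label cannot be
        monophyletic — the pattern that triggers a provisional split."""
        base = "ACGTAC" * 100
        lineage2 = _flip(base, range(1, 145, 6))  # 24 mutations from base
        # each lineage = 2 shared derived mutations (a genuine cherry) plus
        # one private mutation per specimen
        seqs = [
            _flip(base, [0, 6, 300]),
            _flip(base, [0, 6, 306]),
            _flip(lineage2, [2, 8, 302]),
            _flip(lineage2, [2, 8, 308]),
            _flip(base, range(12, 90, 6)),  # beta: 13 mutations off base
            _flip(base, range(12, 90, 6)),
            _flip(lineage2, range(15, 105, 6)),  # gamma: 15 off lineage 2
            _flip(lineage2, range(15, 105, 6)),
        ]
        labels = ["Genus alpha"] * 4 + ["Genus beta"] * 2 + ["Genus gamma"] * 2
        return make_library(seqs, labels)

    def test_two_lineages_split_into_provisional_taxa(self, interleaved_library):
        lib = interleaved_library
        m = distance_matrix(lib)
        tree = bootstrap_supports(lib, n_reps=50, seed=31)
        coh = species_cohesion(tree, lib.labels())
        assert not coh["Genus alpha"]["cohesive"]
        split = sub_cluster_split("Genus alpha", tree, lib.labels(), m)
        assert split is not None
        assert split.groups == [["S1", "S2"], ["S3", "S4"]]
        assert set(split.provisional_labels.values()) == {
            "Genus alpha 1",
            "Genus alpha 2",
        }

    def test_substitution_count_matches_injected_divergence(
        self, interleaved_library
    ):
        lib = interleaved_library
        m = distance_matrix(lib)
        tree = bootstrap_supports(lib, n_reps=50, seed=31)
        split = sub_cluster_split("Genus alpha", tree, lib.labels(), m)
        # cross-lineage pairs differ by 24 (stem) + 3 + 3 (lineage-specific)
        assert split.n_substitutions == 30
        assert split.percent_divergence == pytest.approx(30 / 600 * 100)

    def test_cohesive_species_is_a_no_op(self, two_species_library):
        m = distance_matrix(two_species_library)
        tree = nj_tree(m)
        labels = two_species_library.labels()
        assert sub_cluster_split("Genus alpha", tree, labels, m) is None
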