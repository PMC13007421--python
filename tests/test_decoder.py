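"""Detection-matrix transcription, decoding and distinguishability analysis."""

import itertools
import random

import pytest

from gmoscreen.ce import MarkerCall
from gmoscreen.decoder import (
    DetectionMatrix, analyze_matrix, builtin_matrix, decode, load_matrix,
    save_matrix,
)


def _calls(matrix, positives, indeterminate=()):
    out = []
    for m in matrix.markers:
        if m in indeterminate:
            out.append(MarkerCall(assay=m, call="?"))
        else:
            out.append(MarkerCall(assay=m, call="+" if m in positives else "-"))
    return out


ENDO_POS = MarkerCall(assay="endo", call="+")
ENDO_NEG = MarkerCall(assay="endo", call="-")


class TestBuiltinMatrix:
    def test_dimensions(self, soy_matrix, maize_matrix):
        assert (len(soy_matrix.events), len(soy_matrix.markers)) == (12, 11)
        assert (len(maize_matrix.events), len(maize_matrix.markers)) == (6, 9)

    def test_profile_spot_checks(self, soy_matrix, maize_matrix):
        assert soy_matrix.profiles["Mon87769"] == {"T-E9", "T-tml"}
        assert maize_matrix.profiles["Bt176"] == {"bar"}
        assert maize_matrix.profiles["NK603"] == {"CP4epsps", "P-act1"}

    def test_untested_markers(self, soy_matrix, maize_matrix):
        assert soy_matrix.untested == {"DMO"}
        assert maize_matrix.untested == {"gat4621", "T-hsp17.3", "T-PinII"}
        assert (soy_matrix.untested | maize_matrix.untested) == {
            "DMO", "gat4621", "T-hsp17.3", "T-PinII"
        }

    def test_untested_rows_are_blank(self, soy_matrix, maize_matrix):
        for matrix in (soy_matrix, maize_matrix):
            for m in matrix.untested:
                assert all(m not in matrix.profiles[e] for e in matrix.events)


class TestDecode:
    def test_single_event(self, maize_matrix):
        r = decode(_calls(maize_matrix, {"CP4epsps", "P-act1"}), ENDO_POS,
                   maize_matrix)
        assert r.gm_status == "GM"
        assert r.single_event_candidates == ("NK603",)
        assert r.ambiguity_group == ()

    def test_ambiguity_group(self, maize_matrix):
        r = decode(_calls(maize_matrix, {"pat"}), ENDO_POS, maize_matrix)
        assert set(r.single_event_candidates) == {"T25", "TC1507"}
        assert len(r.ambiguity_group) == 2

    def test_non_gm(self, soy_matrix):
        r = decode(_calls(soy_matrix, set()), ENDO_POS, soy_matrix)
        assert r.gm_status == "non-GM"
        assert r.single_event_candidates == ()

    def test_invalid_without_species(self, soy_matrix):
        r = decode(_calls(soy_matrix, {"pat"}), ENDO_NEG, soy_matrix)
        assert r.gm_status == "invalid"
        assert not r.species_confirmed

    def test_minimal_mixture(self, soy_matrix):
        r = decode(_calls(soy_matrix, {"csr1-2", "T-PinII"}), ENDO_POS,
                   soy_matrix)
        assert r.single_event_candidates == ()
        assert r.minimal_mixtures == (frozenset({"CV127", "DP356043"}),)

    def test_untested_marker_positive_is_unexplained(self, soy_matrix):
        r = decode(_calls(soy_matrix, {"DMO"}), ENDO_POS, soy_matrix)
        assert r.unexplained_markers == {"DMO"}
        assert r.single_event_candidates == ()
        assert any("no reference event" in n for n in r.notes)

    def test_unknown_marker_is_error(self, soy_matrix):
        with pytest.raises(KeyError):
            decode([MarkerCall(assay="bar", call="+")], ENDO_POS, soy_matrix)

    def test_order_independent(self, soy_matrix):
        calls = _calls(soy_matrix, {"pat", "P-ubi10"})
        ref = decode(calls, ENDO_POS, soy_matrix)
        rng = random.Random(1)
        for _ in range(5):
            shuffled = calls[:]
            rng.shuffle(shuffled)
            assert decode(shuffled, ENDO_POS, soy_matrix) == ref

    def test_indeterminate_markers_are_masked(self, soy_matrix):
        """Profile values at indeterminate markers never affect the result."""
        indet = {"T-35S", "T-tml"}
        calls = _calls(soy_matrix, {"pat", "P-ubi10"}, indeterminate=indet)
        ref = decode(calls, ENDO_POS, soy_matrix)
        # mutate the matrix at the indeterminate markers: add them everywhere
        mutated = DetectionMatrix(
            crop=soy_matrix.crop, events=soy_matrix.events,
            markers=soy_matrix.markers,
            profiles={e: p | indet for e, p in soy_matrix.profiles.items()},
            untested=soy_matrix.untested,
        )
        got = decode(calls, ENDO_POS, mutated)
        assert got.single_event_candidates == ref.single_event_candidates
        assert got.minimal_mixtures == ref.minimal_mixtures


def _oracle_minimal_covers(matrix, target):
    """Exhaustive oracle over all 2^n event subsets."""
    covers = []
    for k in range(1, len(matrix.events) + 1):
        for combo in itertools.combinations(matrix.events, k):
            profs = [matrix.profiles[e] for e in combo]
            if any(not p <= target for p in profs):
                continue
            if frozenset().union(*profs) == target:
                covers.append(frozenset(combo))
    minimal = {c for c in covers if not any(o < c for o in covers)}
    return minimal


@pytest.mark.parametrize("crop", ["soybean", "maize"])
def test_mixtures_match_exhaustive_oracle(crop, soy_matrix, maize_matrix):
    matrix = soy_matrix if crop == "soybean" else maize_matrix
    testable = sorted(set(matrix.markers) - matrix.untested)
    rng = random.Random(7)
    for _ in range(20):
        target = frozenset(rng.sample(testable, rng.randint(1, 4)))
        r = decode(_calls(matrix, target), ENDO_POS, matrix)
        if r.single_event_candidates:
            continue  # mixtures only searched when no exact single event
        got = set(r.minimal_mixtures)
        want = _oracle_minimal_covers(matrix, target - r.unexplained_markers)
        assert got == want, target
        for mix in got:  # each cover actually unions to the target
            union = frozenset().union(*(matrix.profiles[e] for e in mix))
            assert union == target - r.unexplained_markers


class TestAnalyze:
    def test_soybean_profile_collisions(self, soy_matrix):
        rep = analyze_matrix(soy_matrix)
        assert rep.n_events == 12
        assert rep.n_distinct_profiles == 10
        groups = {frozenset(g) for g in rep.identical_groups}
        assert groups == {
            frozenset({"DAS68416-4", "DAS81419"}),
            frozenset({"Mon87705", "Mon89788"}),
        }

    def test_maize_profile_collisions(self, maize_matrix):
        rep = analyze_matrix(maize_matrix)
        assert {frozenset(g) for g in rep.identical_groups} == {
            frozenset({"T25", "TC1507"})
        }

    def test_subset_pairs_flag_masking_risk(self, soy_matrix):
        rep = analyze_matrix(soy_matrix)
        assert ("SYHT0H2", "A2704-12") in rep.subset_pairs
        assert ("FG72", "DAS44406-6") in rep.subset_pairs

    def test_diagonal_matrix_fully_distinct(self):
        events = [f"e{i}" for i in range(4)]
        markers = [f"m{i}" for i in range(4)]
        diag = DetectionMatrix(
            crop="maize", events=events, markers=markers,
            profiles={e: frozenset({m}) for e, m in zip(events, markers)},
        )
        rep = analyze_matrix(diag)
        assert rep.n_distinct_profiles == 4
        assert rep.identical_groups == ()
        assert rep.subset_pairs == ()


def test_matrix_round_trip(tmp_path, soy_matrix, maize_matrix):
    for matrix in (soy_matrix, maize_matrix):
        path = tmp_path / f"{matrix.crop}.csv"
        save_matrix(matrix, path)
        # untested markers flagged with '*' in the header
        header = path.read_text().splitlines()[0]
        for m in matrix.untested:
            assert f"{m}*" in header
        loaded = load_matrix(path, crop=matrix.crop)
        assert loaded.events == matrix.events
        assert loaded.markers == matrix.markers
        assert loaded.profiles == matrix.profiles
        assert loaded.untested == matrix.untested
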