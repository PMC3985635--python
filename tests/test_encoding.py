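"""Conservation scoring, morphological encoding, NEXUS, activity calls."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnhl.encoding import (
    DEFAULT_POSITION_SPECS,
    ENDONUCLEASE,
    EXONUCLEASE,
    INDETERMINATE,
    CharacterColumn,
    CharacterMatrix,
    CorePositionSpec,
    NexusMCMCBlock,
    WeightScheme,
    build_combined_matrix,
    classify_activity,
    column_frequencies,
    conservation_characters,
    encode_group_character,
    encode_position,
    read_character_nexus,
    write_character_nexus,
)
from rnhl.errors import BoundsError, FormatError, InputError

B5 = next(s for s in DEFAULT_POSITION_SPECS if s.name == "b5")


class TestColumnFrequencies:
    def test_uniform_column(self):
        assert column_frequencies(["D" * 5] * 10, 2) == {"D": 1.0}

    def test_gaps_count_in_denominator(self):
        rows = ["D"] * 5 + ["-"] * 5
        assert column_frequencies(rows, 0) == {"D": 0.5, "-": 0.5}

    def test_out_of_range_column(self):
        with pytest.raises(BoundsError):
            column_frequencies(["ACD"], 3)

    def test_matches_hand_count(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY-")
        rows = ["".join(rng.choice(aa, 8)) for _ in range(50)]
        freqs = column_frequencies(rows, 3)
        tally = Counter(r[3] for r in rows)
        assert freqs == {k: v / 50 for k, v in tally.items()}


class TestEncodePosition:
    def test_asp_conserved_glu_not(self):
        """Asp >50%, Glu <50% at the resolvase/exonuclease b5 position
        encodes as the three-character vector 1-1-0."""
        assert encode_position({"D": 0.8, "E": 0.1}, B5) == [1, 1, 0]

    def test_nothing_conserved(self):
        freqs = {a: 0.05 for a in "ACDEFGHIKLMNPQRSTVWY"}
        assert encode_position(freqs, B5) == [0, 0, 0]

    def test_jointly_conserved_but_neither_residue_dominant(self):
        # D+E = 0.6 > 0.5 but neither alone above the cutoff
        assert encode_position({"D": 0.3, "E": 0.3}, B5) == [1, 0, 0]

    def test_exactly_half_is_not_conserved(self):
        assert encode_position({"D": 0.5}, B5) == [0, 0, 0]

    def test_default_table_emits_twenty_characters(self):
        assert sum(s.n_characters for s in DEFAULT_POSITION_SPECS) == 20

    @given(
        d=st.floats(0, 1),
        e=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_presence_dominates_residue_characters(self, d, e):
        """If any residue-specific character fires, the presence character
        must fire too (combined frequency >= the single frequency)."""
        if d + e > 1:
            return
        vec = encode_position({"D": d, "E": e}, B5)
        if any(vec[1:]):
            assert vec[0] == 1


class TestGroupCharacter:
    def test_two_groups(self):
        groups = {"f1": "A", "f2": "A", "f3": "B", "f4": "B"}
        assert encode_group_character(groups) == {"f1": 0, "f2": 0, "f3": 1, "f4": 1}

    def test_single_group_constant(self):
        out = encode_group_character({f"f{i}": "only" for i in range(5)})
        assert set(out.values()) == {0}

    def test_state_sharing_equals_group_sharing(self, rng):
        fams = [f"f{i}" for i in range(30)]
        groups = {f: int(rng.integers(0, 6)) for f in fams}
        states = encode_group_character(groups)
        for a in fams:
            for b in fams:
                assert (states[a] == states[b]) == (groups[a] == groups[b])


class TestCombinedMatrix:
    def _inputs(self, L=100, taxa=("t1", "t2", "t3")):
        core = {t: "ACDEFGHIKL" * (L // 10) for t in taxa}
        cons = {t: [i % 2 for i in range(20)] for t in taxa}
        group = {t: 0 for t in taxa}
        return core, cons, group

    def test_default_weights_width(self):
        core, cons, group = self._inputs()
        m = build_combined_matrix(core, cons, group)
        assert m.expanded_width == 100 + 60 + 20

    def test_unit_weights_width(self):
        core, cons, group = self._inputs()
        m = build_combined_matrix(core, cons, group, WeightScheme(1, 1))
        assert m.expanded_width == 100 + 21

    def test_group_column_multiplied_twenty_times(self):
        core, cons, group = self._inputs()
        m = build_combined_matrix(core, cons, group)
        group_cols = [c for c in m.columns if c.kind == "similarity_group"]
        assert len(group_cols) == 1 and group_cols[0].multiplicity == 20

    def test_taxon_mismatch_reported(self):
        core, cons, group = self._inputs()
        del cons["t2"]
        cons["OTHER"] = [0] * 20
        with pytest.raises(InputError, match="OTHER"):
            build_combined_matrix(core, cons, group)


class TestNexusRoundTrip:
    def test_tiny_matrix_round_trips(self):
        m = CharacterMatrix(
            taxa=("a", "b"),
            columns=(
                CharacterColumn("sequence", ("A", "C"), 1),
                CharacterColumn("conservation", ("1", "0"), 3),
            ),
        )
        text = write_character_nexus(m)
        m2, mcmc = read_character_nexus(text)
        assert m2 == m

    def test_defaults_carry_paper_mcmc_settings(self):
        m = CharacterMatrix(
            taxa=("a", "b"),
            columns=(CharacterColumn("sequence", ("A", "C"), 1),),
        )
        text = write_character_nexus(m)
        _, mcmc = read_character_nexus(text)
        assert mcmc.ngen == 10_000_000
        assert mcmc.burnin_fraction == 0.25
        assert "ngen=10000000" in text

    def test_multiplied_columns_physically_duplicated(self):
        core = {"t1": "ACDE", "t2": "ACDF", "t3": "ACDG"}
        cons = {t: [1] * 20 for t in core}
        group = {"t1": 0, "t2": 0, "t3": 1}
        m = build_combined_matrix(core, cons, group)
        text = write_character_nexus(m)
        line = next(
            l for l in text.splitlines() if l.strip().startswith("t1")
        )
        row = line.split()[1]
        assert len(row) == 4 + 60 + 20
        assert row.endswith("0" * 20)  # the group state repeated 20x

    def test_full_combined_matrix_round_trips(self, small_dataset):
        ds = small_dataset
        core = {f: next(iter(rows.values())) for f, rows in ds.alignments.items()}
        cons = {
            f: conservation_characters(rows, ds.position_columns)
            for f, rows in ds.alignments.items()
        }
        group = encode_group_character(ds.clade_truth)
        m = build_combined_matrix(core, cons, group)
        m2, _ = read_character_nexus(write_character_nexus(m))
        assert m2 == m

    def test_too_many_states_rejected(self):
        cols = (CharacterColumn("similarity_group", tuple("0123456789A"), 1),)
        m = CharacterMatrix(taxa=tuple(f"t{i}" for i in range(11)), columns=cols)
        with pytest.raises(FormatError):
            write_character_nexus(m)


class TestClassifyActivity:
    def test_exonuclease_pattern(self):
        profile = {"b1_exo": True, "a2": True, "b4": False, "b5": False}
        verdict, report = classify_activity(profile, "reversed")
        assert verdict == EXONUCLEASE
        assert any("exo" in v for _, v in report)

    def test_all_indicators_absent(self):
        profile = {"b1_exo": False, "a2": False, "b4": False, "b5": False}
        verdict, _ = classify_activity(profile, "unknown")
        assert verdict == INDETERMINATE

    def test_endonuclease_pattern(self):
        profile = {"b1_exo": False, "a2": False, "b4": True, "b5": False}
        verdict, _ = classify_activity(profile, "parallel_to_b1")
        assert verdict == ENDONUCLEASE

    def test_single_indicator_is_indeterminate(self):
        profile = {"b1_exo": True, "a2": False, "b4": False, "b5": False}
        verdict, _ = classify_activity(profile, "unknown")
        assert verdict == INDETERMINATE

    def test_synthetic_exo_families_called_exonuclease(self):
        """Families simulated with the exonuclease motif pattern at 0.9
        presence are classified exonuclease-like in >= 95% of cases."""
        from rnhl.encoding import conserved_positions
        from rnhl.synthetic import SuperfamilyConfig, simulate_superfamily

        exo_positions = {"b1", "b1_exo", "a2", "b5"}
        for seed in range(3):
            n_fam = 67  # ~200 families over the three seeds
            fams = [f"F{i + 1:03d}" for i in range(n_fam)]
            presence = {
                (f, s.name): (0.9 if s.name in exo_positions else 0.0)
                for f in fams
                for s in DEFAULT_POSITION_SPECS
            }
            cfg = SuperfamilyConfig(
                n_families=n_fam,
                seqs_per_family=8,
                core_length=60,
                clade_partition={f: "exo" for f in fams},
                motif_presence=presence,
                seed=seed,
            )
            ds = simulate_superfamily(cfg)
            calls = []
            for rows in ds.alignments.values():
                flags = conserved_positions(rows, ds.position_columns)
                verdict, _ = classify_activity(flags, "reversed")
                calls.append(verdict)
            frac = sum(v == EXONUCLEASE for v in calls) / len(calls)
            assert frac >= 0.95
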