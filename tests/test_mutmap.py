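import io

import numpy as np
import pytest

from mutsphere import mutmap, synthetic
from mutsphere.geometry import load_structure, write_pdb
from mutsphere.mutmap import (
    MutationRecord,
    MutationTableError,
    ReconciliationError,
    filter_mutations,
    is_blank,
    read_mutation_table,
    reconcile,
    tally,
    write_mutation_table,
)


def rec(**kw):
    base = dict(
        gene="G1", sample_id="S1", position=5, wt_aa="A", mut_aa="V",
        mutation_type="missense", somatic_status="confirmed somatic variant",
        screen_type="whole_genome",
    )
    base.update(kw)
    return MutationRecord(**base)


def identity_model(n, seed=0):
    spec = synthetic.FixtureSpec(geometry="linear", N=n, seed=seed)
    model, _ = synthetic.make_structure(spec)
    return model


def identity_mapping(n):
    return mutmap.ResidueMapping(
        pairs={i: i for i in range(1, n + 1)}, mode="structure_numbering"
    )


class TestFilter:
    def test_accepted_statuses_kept(self):
        kept = filter_mutations(
            [
                rec(somatic_status="confirmed somatic variant"),
                rec(
                    sample_id="S2",
                    somatic_status="Reported in another cancer sample as somatic",
                ),
            ]
        )
        assert len(kept) == 2

    def test_status_match_is_case_insensitive_and_trimmed(self):
        kept = filter_mutations([rec(somatic_status="  Confirmed Somatic Variant ")])
        assert len(kept) == 1

    @pytest.mark.parametrize("mtype", ["nonsense", "synonymous", "indel", "other"])
    def test_non_missense_dropped(self, mtype):
        r = rec(mutation_type=mtype, mut_aa="A" if mtype == "synonymous" else "V")
        assert filter_mutations([r]) == []

    def test_unknown_status_or_screen_dropped(self):
        assert filter_mutations([rec(somatic_status="variant of unknown origin")]) == []
        assert filter_mutations([rec(screen_type="other")]) == []

    def test_duplicates_removed_keeping_first(self):
        rows = [
            rec(sample_id="S1", position=5),
            rec(sample_id="S1", position=5),  # byte-identical duplicate
            rec(sample_id="S2", position=5),  # different sample: kept
            rec(sample_id="S1", position=6),  # different site: kept
            rec(sample_id="S1", position=5, mut_aa="G"),  # different substitution
        ]
        kept = filter_mutations(rows)
        assert len(kept) == 4
        assert kept[0] is rows[0]

    def test_order_independence_of_tally(self):
        model = identity_model(30)
        mapping = identity_mapping(30)
        rows = [rec(sample_id=f"S{i}", position=1 + i % 7) for i in range(20)]
        t1 = tally(filter_mutations(rows), mapping, model)
        t2 = tally(filter_mutations(rows[::-1]), mapping, model)
        assert t1.counts == t2.counts


class TestTableIO:
    def test_round_trip(self, tmp_path):
        rows = [rec(), rec(sample_id="S2", position=9, wt_aa="G", mut_aa="R")]
        path = tmp_path / "muts.tsv"
        write_mutation_table(rows, path)
        assert read_mutation_table(path) == rows

    def test_malformed_rows_reported_with_numbers(self):
        text = (
            "gene\tsample_id\tposition\twt_aa\tmut_aa\tmutation_type\t"
            "somatic_status\tscreen_type\n"
            "G1\tS1\t5\tA\tV\tmissense\tconfirmed somatic variant\twhole_genome\n"
            "G1\tS2\t0\tA\tV\tmissense\tconfirmed somatic variant\twhole_genome\n"
            "G1\tS3\t7\tJ\tV\tmissense\tconfirmed somatic variant\twhole_genome\n"
        )
        with pytest.raises(MutationTableError) as err:
            read_mutation_table(io.StringIO(text))
        msg = str(err.value)
        assert "row 2" in msg and "row 3" in msg and "row 1" not in msg

    def test_missing_column(self):
        with pytest.raises(MutationTableError):
            read_mutation_table(io.StringIO("gene\tsample_id\nG1\tS1\n"))


class TestReconcile:
    def test_identical_sequences_identity_mapping(self):
        model = identity_model(40)
        mapping = reconcile(model.sequence, model, mode="alignment")
        assert mapping.alignment_identity == pytest.approx(1.0)
        assert mapping.pairs == {i: i for i in range(1, 41)}

    def test_truncated_structure_is_offset_map(self):
        model = identity_model(50)
        canonical = model.sequence
        truncated = load_structure(
            write_pdb(canonical[5:], model.coords[5:], start_number=1)
        )
        mapping = reconcile(canonical, truncated, mode="alignment")
        for p in range(6, 51):
            assert mapping.pairs[p] == p - 5
        for p in range(1, 6):
            assert p not in mapping.pairs

    def test_identity_floor(self):
        model = identity_model(30, seed=1)
        other = identity_model(30, seed=99)  # unrelated random sequence
        with pytest.raises(ReconciliationError):
            reconcile(other.sequence, model, mode="alignment")

    def test_structure_numbering_mode(self):
        model = load_structure(write_pdb("ACD", np.eye(3) * 10, start_number=7))
        mapping = reconcile(None, model, mode="structure_numbering")
        assert mapping.pairs == {7: 1, 8: 2, 9: 3}

    def test_alignment_requires_sequence(self):
        model = identity_model(10)
        with pytest.raises(ReconciliationError):
            reconcile(None, model, mode="alignment")


class TestTally:
    def test_three_sample_example(self):
        # samples A: {5, 20}, B: {6, 21}, C: {5}  ->  five occurrences
        model = identity_model(25)
        mapping = identity_mapping(25)
        rows = [
            rec(sample_id="A", position=5),
            rec(sample_id="A", position=20),
            rec(sample_id="B", position=6),
            rec(sample_id="B", position=21),
            rec(sample_id="C", position=5),
        ]
        t = tally(filter_mutations(rows), mapping, model)
        assert t.counts == {5: 2, 6: 1, 20: 1, 21: 1}
        assert t.total == 5
        # two spheres covering {5,6} and {20,21} capture all five occurrences
        assert t.structure_counts[[4, 5, 19, 20]].sum() == 5

    def test_empty(self):
        model = identity_model(5)
        t = tally([], identity_mapping(5), model)
        assert t.total == 0 and t.counts == {}

    def test_unmapped_positions_dropped_and_counted(self):
        model = identity_model(10)
        mapping = mutmap.ResidueMapping(
            pairs={i: i for i in range(1, 6)}, mode="structure_numbering"
        )
        rows = [rec(sample_id=f"S{i}", position=p) for i, p in enumerate([3, 3, 8])]
        t = tally(rows, mapping, model)
        assert t.total == 2
        assert t.dropped_unmapped == 1
        assert t.total + t.dropped_unmapped == len(rows)

    def test_repeated_residue(self):
        model = identity_model(10)
        rows = [rec(sample_id=f"S{i}", position=4) for i in range(3)]
        t = tally(rows, identity_mapping(10), model)
        assert t.counts == {4: 3}


class TestBlank:
    @pytest.mark.parametrize("total,expected", [(0, True), (1, True), (2, False)])
    def test_threshold(self, total, expected):
        model = identity_model(10)
        rows = [rec(sample_id=f"S{i}", position=4) for i in range(total)]
        t = tally(rows, identity_mapping(10), model)
        assert is_blank(t) is expected
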