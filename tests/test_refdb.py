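"""Reference-database construction: differentials, signed ranks, grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmap import (
    ExpressionInstance,
    GroupBy,
    ReferenceDatabase,
    TreatmentSetKey,
    build_database,
    differential_profile,
    read_expression_dataset,
    signed_rank,
)
from conftest import plate_instances


def _inst(iid, values, plate="PL0", pert="drug", cell="CL1", control=False):
    return ExpressionInstance(
        instance_id=iid,
        values=np.asarray(values, float),
        plate_id=plate,
        perturbagen=pert,
        cell_line=cell,
        is_control=control,
    )


class TestDifferentialProfile:
    def test_mean_of_controls(self):
        treated = _inst("t", [2, 0, 1])
        controls = [_inst("c1", [1, 0, 1], control=True), _inst("c2", [1, 0, 3], control=True)]
        assert differential_profile(treated, controls).tolist() == [1.0, 0.0, -1.0]

    def test_identity_against_self(self):
        treated = _inst("t", [0.3, -1.2, 4.0])
        ctl = _inst("c", [0.3, -1.2, 4.0], control=True)
        assert differential_profile(treated, [ctl]).tolist() == [0.0, 0.0, 0.0]

    def test_median_aggregate(self):
        treated = _inst("t", [4.0])
        controls = [_inst(f"c{i}", [v], control=True) for i, v in enumerate([0, 1, 10])]
        assert differential_profile(treated, controls, aggregate="median")[0] == 3.0

    def test_cross_plate_control_rejected(self):
        treated = _inst("t", [1.0], plate="PL0")
        ctl = _inst("c", [1.0], plate="PL1", control=True)
        with pytest.raises(ValueError, match="PL1"):
            differential_profile(treated, [ctl])

    def test_empty_controls_names_plate(self):
        with pytest.raises(ValueError, match="PL0"):
            differential_profile(_inst("t", [1.0]), [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="values"):
            differential_profile(_inst("t", [1, 2]), [_inst("c", [1.0], control=True)])


class TestSignedRank:
    @pytest.mark.parametrize(
        "d, expected",
        [
            ([0.5, -2.0, 1.0], [1, -3, 2]),
            ([-1, -2, -3], [-1, -2, -3]),
            ([3, -1, 2], [3, -1, 2]),  # already a signed permutation
        ],
    )
    def test_examples(self, d, expected):
        assert signed_rank(d).tolist() == expected

    def test_ties_broken_by_probe_index_and_zero_is_positive(self):
        # ties (two zeros) keep input order; sign(0) = +
        assert signed_rank([0.0, 0.0, -1.0]).tolist() == [1, 2, -3]

    def test_idempotent_on_rank_valued_input(self, rng):
        d = (rng.permutation(20) + 1) * rng.choice([-1, 1], 20)
        assert np.array_equal(signed_rank(d.astype(float)), d)

    # magnitudes bounded so that cubing neither underflows to zero nor
    # overflows: underflow would flip the sign of a tiny negative value
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=1,
            max_size=60,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_permutation_property_and_monotone_invariance(self, d):
        r = signed_rank(d)
        assert sorted(np.abs(r)) == list(range(1, len(d) + 1))
        # any strictly increasing odd map of the differentials (x^3) keeps ranks
        cubed = signed_rank([x**3 for x in d])
        assert np.array_equal(r, cubed)


class TestBuildDatabase:
    def test_profile_count_and_controls_consumed(self):
        db = build_database(plate_instances(n_treated=2, n_controls=2), [f"p{i}" for i in range(6)])
        assert db.n_profiles == 2
        assert all(not i.startswith("PL0_ctl") for i in db.instance_ids)

    def test_no_treated_instances(self):
        only_ctl = [i for i in plate_instances() if i.is_control]
        with pytest.raises(ValueError, match="non-control"):
            build_database(only_ctl, [f"p{i}" for i in range(6)])

    def test_missing_controls_lists_offenders(self):
        insts = plate_instances()
        orphan = _inst("lost", np.zeros(6), plate="PL9")
        with pytest.raises(ValueError, match="lost"):
            build_database(insts + [orphan], [f"p{i}" for i in range(6)])

    def test_round_trip(self, tmp_path):
        db = build_database(plate_instances(n_treated=3), [f"p{i}" for i in range(6)])
        db.save(tmp_path / "db")
        back = ReferenceDatabase.load(tmp_path / "db")
        assert back.probe_ids == db.probe_ids
        assert np.array_equal(back.ranks, db.ranks)
        assert back.meta.equals(db.meta)


class TestGrouping:
    def _db(self):
        insts = plate_instances(n_treated=3, n_controls=1)
        for inst, (p, c) in zip(
            (i for i in insts if not i.is_control),
            [("A", "X"), ("A", "X"), ("A", "Y")],
        ):
            inst.perturbagen, inst.cell_line = p, c
        return build_database(insts, [f"p{i}" for i in range(6)])

    def test_by_drug_and_cell_line(self):
        sets = self._db().group_sets(GroupBy.DRUG_AND_CELL_LINE)
        sizes = {k: len(v) for k, v in sets.items()}
        assert sizes == {TreatmentSetKey("A", "X"): 2, TreatmentSetKey("A", "Y"): 1}

    def test_by_drug(self):
        sets = self._db().group_sets(GroupBy.DRUG)
        assert {k: len(v) for k, v in sets.items()} == {TreatmentSetKey("A"): 3}

    def test_partition_and_nesting(self):
        db = self._db()
        fine = db.group_sets(GroupBy.DRUG_AND_CELL_LINE)
        coarse = db.group_sets(GroupBy.DRUG)
        members = [i for v in fine.values() for i in v]
        assert sorted(members) == sorted(db.instance_ids)  # disjoint + covering
        for key, ids in coarse.items():
            fine_union = [
                i for k, v in fine.items() if k.perturbagen == key.perturbagen for i in v
            ]
            assert sorted(fine_union) == sorted(ids)

    def test_empty_cell_line_is_distinct(self):
        insts = plate_instances(n_treated=2, n_controls=1)
        treated = [i for i in insts if not i.is_control]
        treated[0].perturbagen = treated[1].perturbagen = "A"
        treated[0].cell_line, treated[1].cell_line = "", "X"
        db = build_database(insts, [f"p{i}" for i in range(6)])
        assert len(db.group_sets(GroupBy.DRUG_AND_CELL_LINE)) == 2


class TestCompoundFilter:
    def _db(self):
        insts = plate_instances(n_treated=5, n_controls=1)
        for inst, p in zip((i for i in insts if not i.is_control), "AABBB"):
            inst.perturbagen = p
        return build_database(insts, [f"p{i}" for i in range(6)])

    def test_identity_and_subset(self):
        db = self._db()
        assert db.filter_by_compound_list({"A", "B"}).n_profiles == 5
        sub = db.filter_by_compound_list({"A"})
        assert sub.n_profiles == 2
        assert sub.probe_ids == db.probe_ids

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="no profiles"):
            self._db().filter_by_compound_list(set())

    def test_case_folding_off_by_default(self):
        db = self._db()
        with pytest.raises(ValueError):
            db.filter_by_compound_list({"a"})
        assert db.filter_by_compound_list({"a"}, case_fold=True).n_profiles == 2


class TestDatasetIO:
    def test_read_and_build(self, tmp_path):
        probes = [f"p{i}" for i in range(4)]
        expr = pd.DataFrame(
            {"t0": [1.0, 2, 3, 4], "c0": [0.0, 0, 0, 0]}, index=pd.Index(probes, name="probe_id")
        )
        expr.to_csv(tmp_path / "e.tsv", sep="\t")
        meta = pd.DataFrame(
            {
                "instance_id": ["t0", "c0"],
                "perturbagen": ["A", "DMSO"],
                "cell_line": ["X", ""],
                "dose": ["", ""],
                "time": ["", ""],
                "plate_id": ["PL0", "PL0"],
                "is_control": [0, 1],
            }
        )
        meta.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        instances, probe_ids = read_expression_dataset(tmp_path / "e.tsv", tmp_path / "m.tsv")
        assert probe_ids == probes
        db = build_database(instances, probe_ids)
        assert db.n_profiles == 1
        assert db.profile("t0").signed_ranks.tolist() == [1, 2, 3, 4]

    def test_missing_value_names_probe_and_line(self, tmp_path):
        (tmp_path / "e.tsv").write_text("probe_id\tt0\np0\t1.0\np1\t\n")
        (tmp_path / "m.tsv").write_text(
            "instance_id\tperturbagen\tcell_line\tplate_id\tis_control\nt0\tA\tX\tPL0\t0\n"
        )
        with pytest.raises(ValueError, match="p1.*line 3"):
            read_expression_dataset(tmp_path / "e.tsv", tmp_path / "m.tsv")
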