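"""Domain types, table IO and the embedded uptake-table fixture."""

import numpy as np
import pandas as pd
import pytest

from hqsar.data_model import (
    PermeabilityMeasurement,
    apparent_permeability,
    compound_id,
    percent_uptake,
    read_descriptor_table,
    reference_descriptors,
    split_train_test,
    write_descriptor_table,
)

from conftest import make_matrix


class TestPercentUptake:
    @pytest.mark.parametrize(
        "raw,control,expected",
        [
            (29.64, 23.71, 125),  # Caffeine vs the 482R control
            (23.58, 25.92, 91),  # Raloxifene vs the 482T control
            (23.71, 23.71, 100),  # control against itself
            (57.38, 23.71, 242),  # Ciprofloxacin, 482R
            (1.0, 200.0, 1),  # round-half-up of 0.5
        ],
    )
    def test_examples(self, raw, control, expected):
        assert percent_uptake(raw, control) == expected

    def test_round_half_up(self):
        # 100 * 0.605 = 60.5 rounds up, not to even
        assert percent_uptake(0.605, 1.0) == 61

    @pytest.mark.parametrize("raw,control", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_rejected(self, raw, control):
        with pytest.raises(ValueError):
            percent_uptake(raw, control)


class TestApparentPermeability:
    def test_unit_case(self):
        assert apparent_permeability(PermeabilityMeasurement(1, 1, 1)) == 1

    def test_formula(self):
        assert apparent_permeability(PermeabilityMeasurement(2, 4, 0.5)) == 1

    def test_homogeneity_in_donor_concentration(self):
        base = apparent_permeability(PermeabilityMeasurement(3.2, 1.7, 0.4))
        double = apparent_permeability(PermeabilityMeasurement(3.2, 1.7, 0.8))
        assert double == pytest.approx(base / 2)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            PermeabilityMeasurement(1, 0, 1)


class TestTableIO:
    def test_round_trip_bit_for_bit(self, tmp_path, rng):
        vals = rng.standard_normal((5, 4)) * 10.0 ** rng.integers(-6, 6, (5, 4))
        vals[2, 1] = np.nan
        m = make_matrix(vals, n_train=3)
        path = tmp_path / "desc.csv"
        write_descriptor_table(m, path)
        back = read_descriptor_table(path)
        assert back.descriptor_names == m.descriptor_names
        assert [c.id for c in back.compounds] == [c.id for c in m.compounds]
        assert [c.role for c in back.compounds] == [c.role for c in m.compounds]
        a, b = m.values.to_numpy(), back.values.to_numpy()
        assert np.array_equal(a, b, equal_nan=True)  # exact, not approx
        assert back.parse_report.n_missing == 1
        assert back.parse_report.n_unparseable == 0

    def test_blank_and_garbage_cells_counted(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound_id,a,b\nc1,1.5,\nc2,oops,3.0\nc3,2.0,4.0\n")
        m = read_descriptor_table(path)
        assert m.shape == (3, 2)
        assert m.values.isna().sum().sum() == 2
        assert m.parse_report.n_missing == 2
        assert m.parse_report.n_unparseable == 1  # "oops" only; blank is not

    def test_well_formed_small_file(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound_id,a,b\nc1,1,2\nc2,3,4\nc3,5,6\n")
        m = read_descriptor_table(path)
        assert m.shape == (3, 2)
        assert m.values.notna().all().all()

    def test_duplicate_descriptor_name_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound_id,a,a\nc1,1,2\n")
        with pytest.raises(ValueError, match="duplicate descriptor"):
            read_descriptor_table(path)

    def test_duplicate_compound_id_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound_id,a\nc1,1\nc1,2\n")
        with pytest.raises(ValueError, match="duplicate compound"):
            read_descriptor_table(path)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("compound_id\ta\tb\nc1\t1\t2\n")
        assert read_descriptor_table(path).shape == (1, 2)


class TestReferenceTaxonomy:
    def test_class_counts(self):
        metas = reference_descriptors()
        assert len(metas) == 26
        counts = {}
        for m in metas:
            counts[m.dclass] = counts.get(m.dclass, 0) + 1
        assert counts == {
            "constitutional": 8,
            "thermodynamic": 3,
            "electrostatic": 3,
            "quantum_chemical": 12,
        }

    def test_round_trip_through_file(self, tmp_path, rng):
        metas = reference_descriptors()
        vals = rng.standard_normal((3, len(metas)))
        m = make_matrix(vals, names=[d.name for d in metas])
        m.descriptors = metas  # keep the real class labels
        path = tmp_path / "t5.csv"
        write_descriptor_table(m, path)
        back = read_descriptor_table(path)
        assert len(back.descriptors) == 26
        assert back.classes == {d.name: d.dclass for d in metas}


class TestPaperFixture:
    def test_partition_sizes(self, paper_fixture):
        assert len(paper_fixture.training_ids) == 18
        assert len(paper_fixture.test_ids) == 7

    def test_flagged_cells_are_exactly_the_printed_inconsistencies(
        self, paper_fixture
    ):
        flagged = {
            (cid, p)
            for p, rs in paper_fixture.responses.items()
            for cid in rs.flagged
        }
        assert flagged == {
            ("fumitremorginc", "482R"),
            ("caffeine", "482T"),
            ("epinephrine", "482T"),
        }

    def test_unflagged_cells_match_printed_percent(self, paper_fixture):
        for rs in paper_fixture.responses.values():
            ok = rs.table[~rs.table["inconsistent"]]
            diff = (ok["percent_recomputed"] - ok["percent_printed"]).abs()
            assert (diff <= 1).all()

    def test_ciprofloxacin_482r_consistent(self, paper_fixture):
        row = paper_fixture.responses["482R"].table.loc["ciprofloxacin"]
        assert percent_uptake(57.38, 23.71) == 242 == row["percent_printed"]
        assert not row["inconsistent"]

    def test_flagged_rows_keep_printed_value_verbatim(self, paper_fixture):
        row = paper_fixture.responses["482R"].table.loc["fumitremorginc"]
        assert row["raw_rate"] == 26.76
        assert row["percent_printed"] == 305  # never silently corrected
        assert row["percent_recomputed"] == percent_uptake(26.76, 23.71)

    def test_duplicate_assay_gets_distinct_id(self, paper_fixture):
        ids = [c.id for c in paper_fixture.compounds]
        assert "ketoconazole" in ids and "ketoconazole_test" in ids

    def test_compound_id_collapse(self):
        assert compound_id("Rhodamine 123") == "rhodamine123"


class TestSplit:
    def test_paper_roles_give_18_7(self, paper_fixture, rng):
        vals = rng.standard_normal((25, 6))
        m = make_matrix(vals)
        m.compounds = list(paper_fixture.compounds)
        m.values.index = pd.Index([c.id for c in m.compounds])
        train, test = split_train_test(m)
        assert train.shape[0] == 18 and test.shape[0] == 7

    def test_partition_property(self, rng):
        m = make_matrix(rng.standard_normal((10, 3)), n_train=6)
        train, test = split_train_test(m)
        got = set(train.values.index) | set(test.values.index)
        assert got == set(m.values.index)
        assert not (set(train.values.index) & set(test.values.index))
        assert train.descriptor_names == test.descriptor_names == m.descriptor_names

    def test_degenerate_all_training(self, rng):
        m = make_matrix(rng.standard_normal((4, 2)), n_train=4)
        train, test = split_train_test(m)
        assert train.shape[0] == 4 and test.shape[0] == 0

    def test_missing_assignment_rejected(self, rng):
        m = make_matrix(rng.standard_normal((4, 2)), n_train=2)
        with pytest.raises(KeyError):
            split_train_test(m, {"c00": "training"})
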