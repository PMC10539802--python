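"""Restraint parsing, conformity filters, pairing, and cross-tabulations."""

import pandas as pd
import pytest

from aroshift.geometry import parse_structure
from aroshift.nmrstar import load_shifts
from aroshift.restraints import (
    Member,
    RestraintParseError,
    RestraintRecord,
    amide_aromatic_restraints,
    filter_restraints,
    pair_class_table,
    parse_restraints,
    proportion_with_restraint_vs_z,
)
from aroshift.survey import SURVEY_COLUMNS, build_survey

HEADER = """data_demo
save_dist
   _Gen_dist_constraint_list.Sf_category general_distance_constraints
   _Gen_dist_constraint_list.Constraint_type NOE
   loop_
      _Gen_dist_constraint.ID
      _Gen_dist_constraint.Auth_asym_ID_1
      _Gen_dist_constraint.Comp_index_ID_1
      _Gen_dist_constraint.Comp_ID_1
      _Gen_dist_constraint.Atom_ID_1
      _Gen_dist_constraint.Auth_asym_ID_2
      _Gen_dist_constraint.Comp_index_ID_2
      _Gen_dist_constraint.Comp_ID_2
      _Gen_dist_constraint.Atom_ID_2
      _Gen_dist_constraint.Distance_lower_bound_val
      _Gen_dist_constraint.Distance_upper_bound_val
"""
FOOTER = "   stop_\nsave_\n"


def star_file(tmp_path, rows, name="r.str"):
    p = tmp_path / name
    p.write_text(HEADER + "".join(f"      {r}\n" for r in rows) + FOOTER)
    return p


def rec(rid, upper, lower=None, residues=((12, "ALA"), (40, "PHE"))):
    members = [Member("A", seq, rtype, "H" if i == 0 else "HZ")
               for i, (seq, rtype) in enumerate(residues)]
    return RestraintRecord(rid, members, lower, upper, "NOE")


class TestParsing:
    def test_three_rows_three_records(self, tmp_path):
        p = star_file(tmp_path, [
            "1 A 12 ALA H A 40 PHE HZ 1.8 5.0",
            "2 A 13 GLY H A 40 PHE HD1 1.8 4.5",
            "3 A 14 SER H A 23 TRP HE1 1.8 3.5",
        ])
        records = parse_restraints(p)
        assert len(records) == 3
        assert all(r.origin == "NOE" for r in records)
        assert records[0].upper_A == 5.0 and records[0].lower_A == 1.8

    def test_lower_only_kept_at_parse_time(self, tmp_path):
        p = star_file(tmp_path, ["1 A 12 ALA H A 40 PHE HZ 1.8 ."])
        (record,) = parse_restraints(p)
        assert record.upper_A is None and record.lower_A == 1.8

    def test_ambiguous_rows_share_one_record(self, tmp_path):
        p = star_file(tmp_path, [
            "1 A 12 ALA H A 40 PHE HZ 1.8 5.0",
            "1 A 12 ALA H A 44 PHE HZ 1.8 5.0",
            "1 A 12 ALA H A 47 TYR HE1 1.8 5.0",
        ])
        (record,) = parse_restraints(p)
        assert len(record.members) == 4
        assert len(record.distinct_residues()) == 4

    def test_simple_dialect_origin(self, tmp_path):
        text = HEADER.replace("Constraint_type NOE",
                              "Constraint_type 'general distance'")
        p = tmp_path / "simple.str"
        p.write_text(text + "      1 A 12 ALA H A 40 PHE HZ 1.8 5.0\n" + FOOTER)
        (record,) = parse_restraints(p)
        assert record.origin == "simple"

    def test_file_without_constraint_loop_raises_with_reason(self, tmp_path):
        p = tmp_path / "none.str"
        p.write_text("data_x\n_Entry.ID x\n")
        with pytest.raises(RestraintParseError) as err:
            parse_restraints(p)
        assert err.value.reason == "unparseable"


class TestFilter:
    def test_the_three_stated_rules(self):
        records = [
            rec(1, upper=5.5),
            rec(2, upper=6.5),
            rec(3, upper=None, lower=1.8),
            RestraintRecord(4, [
                Member("A", 12, "ALA", "H"), Member("A", 40, "PHE", "HZ"),
                Member("A", 44, "PHE", "HZ"),
            ], 1.8, 4.0, "NOE"),
        ]
        surviving = filter_restraints(records)
        assert [r.restraint_id for r in surviving] == [1]

    def test_boundary_upper_exactly_six_is_kept(self):
        assert filter_restraints([rec(1, upper=6.0)]) != []
        assert filter_restraints([rec(1, upper=6.0 + 1e-9)]) == []

    def test_two_residue_ambiguity_is_not_ambiguous(self):
        r = RestraintRecord(1, [
            Member("A", 12, "ALA", "H"),
            Member("A", 40, "PHE", "HD1"), Member("A", 40, "PHE", "HD2"),
        ], 1.8, 4.0, "NOE")
        assert filter_restraints([r]) == [r]

    def test_empty_input(self):
        assert filter_restraints([]) == []

    def test_idempotent_and_subset(self):
        records = [rec(i, upper=u, lower=l) for i, (u, l) in enumerate(
            [(5.0, 1.8), (None, 1.8), (6.1, None), (3.0, 2.0), (6.0, 1.8)]
        )]
        once = filter_restraints(records)
        assert filter_restraints(once) == once
        assert all(r in records for r in once)


RES_TYPES = {
    ("A", 12): "ALA", ("A", 13): "GLY", ("A", 23): "TRP",
    ("A", 40): "PHE", ("A", 44): "TYR",
}


class TestPairing:
    def test_definitional_pair(self):
        pairs = amide_aromatic_restraints([rec(1, 5.0)], RES_TYPES)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.amide_seq_id, p.ring_seq_id, p.n_restraints) == (12, 40, 1)

    def test_two_restraints_aggregate(self):
        records = [
            RestraintRecord(1, [Member("A", 12, "ALA", "H"),
                                Member("A", 23, "TRP", "HD1")], 1.8, 5.0, "NOE"),
            RestraintRecord(2, [Member("A", 12, "ALA", "H"),
                                Member("A", 23, "TRP", "HE1")], 1.8, 4.0, "NOE"),
        ]
        (pair,) = amide_aromatic_restraints(records, RES_TYPES)
        assert pair.n_restraints == 2

    def test_alpha_proton_is_not_an_amide(self):
        r = RestraintRecord(1, [Member("A", 12, "ALA", "HA"),
                                Member("A", 40, "PHE", "HZ")], 1.8, 5.0, "NOE")
        assert amide_aromatic_restraints([r], RES_TYPES) == []

    def test_pseudoatom_expands_to_ring_set(self):
        r = RestraintRecord(1, [Member("A", 12, "ALA", "H"),
                                Member("A", 44, "TYR", "QE")], 1.8, 5.0, "NOE")
        (pair,) = amide_aromatic_restraints([r], RES_TYPES)
        assert pair.ring_residue_type == "TYR"

    def test_unknown_pseudoatom_skips_record(self, caplog):
        r = RestraintRecord(1, [Member("A", 12, "ALA", "H"),
                                Member("A", 23, "TRP", "QX")], 1.8, 5.0, "NOE")
        with caplog.at_level("WARNING", logger="aroshift"):
            assert amide_aromatic_restraints([r], RES_TYPES) == []
        assert any("pseudoatom" in m for m in caplog.messages)

    def test_unresolvable_member_skips_record(self, caplog):
        r = RestraintRecord(1, [Member("A", 99, "ALA", "H"),
                                Member("A", 40, "PHE", "HZ")], 1.8, 5.0, "NOE")
        with caplog.at_level("WARNING", logger="aroshift"):
            assert amide_aromatic_restraints([r], RES_TYPES) == []

    def test_counts_match_brute_force_rescan(self, stats, mixed_entry):
        ens = parse_structure(mixed_entry["structure"])
        records = filter_restraints(parse_restraints(mixed_entry["restraints"]))
        pairs = amide_aromatic_restraints(records, ens.residue_types())
        from aroshift.reference_stats import AMIDE_H_NAMES
        from aroshift.restraints import RING_H_NAMES
        for pair in pairs:
            n = 0
            for r in records:
                has_amide = any(
                    m.seq_id == pair.amide_seq_id and m.atom_name in AMIDE_H_NAMES
                    for m in r.members
                )
                has_ring = any(
                    m.seq_id == pair.ring_seq_id
                    and m.atom_name in RING_H_NAMES.get(m.residue_type, ())
                    for m in r.members
                )
                n += has_amide and has_ring
            assert n == pair.n_restraints


def survey_frame(rows):
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def srow(seq, z, rtype="ALA"):
    return {
        "entry_id": "E", "chain": "A", "seq_id": seq, "residue_type": rtype,
        "shift_ppm": 8.0, "z": z, "distance_A": 5.0, "azimuth_deg": 30.0,
        "ring_chain": "A", "ring_seq_id": 40, "ring_residue_type": "PHE",
        "ring_label": "six",
    }


def mkpair(amide_seq, ring_seq=40, ring_type="PHE", n=1):
    from aroshift.restraints import RestrainedPair
    return RestrainedPair("A", amide_seq, "ALA", "A", ring_seq, ring_type, n)


class TestProportions:
    def test_simple_ratio(self):
        df = survey_frame([srow(i, 0.2) for i in range(1, 11)])
        pairs = [mkpair(i) for i in (1, 2, 3)]
        out = proportion_with_restraint_vs_z({"E": df}, {"E": pairs})
        row = out[out["z_bin"] == 0].iloc[0]
        assert row["n_amides"] == 10 and row["n_restrained"] == 3
        assert row["proportion"] == pytest.approx(0.3)

    def test_entries_without_pairs_excluded_from_denominator(self):
        df1 = survey_frame([srow(i, 0.0) for i in range(1, 6)])
        df2 = survey_frame([srow(i, 0.0) for i in range(1, 21)])
        pairs1 = [mkpair(1)]
        out = proportion_with_restraint_vs_z(
            {"E1": df1, "E2": df2}, {"E1": pairs1, "E2": []}
        )
        assert out[out["z_bin"] == 0]["n_amides"].iloc[0] == 5

    def test_empty_bins_absent_not_zero(self):
        df = survey_frame([srow(1, 0.1)])
        out = proportion_with_restraint_vs_z({"E": df}, {"E": [mkpair(1)]})
        assert set(out["z_bin"]) == {0}

    def test_proportions_bounded(self):
        df = survey_frame([srow(i, z) for i, z in enumerate([-4.2, -4.0, 0.1, 3.9], 1)])
        pairs = [mkpair(1), mkpair(2), mkpair(4)]
        out = proportion_with_restraint_vs_z({"E": df}, {"E": pairs})
        assert ((out["proportion"] >= 0) & (out["proportion"] <= 1)).all()
        assert (out["n_restrained"] <= out["n_amides"]).all()


class TestPairClassTable:
    def test_single_pair_placement(self):
        df = survey_frame([srow(5, -3.1)])
        table = pair_class_table([mkpair(5)], df)
        hit = table[(table["ring_residue_type"] == "PHE")
                    & (table["z_class"] == "upfield")
                    & (table["n_restraints"] == 1)]
        assert hit["count"].iloc[0] == 1
        assert table["count"].sum() == 1

    def test_zero_pairs_full_skeleton(self):
        table = pair_class_table([], survey_frame([]))
        assert len(table) == 4 * 3  # ring types x classes, single n column
        assert (table["count"] == 0).all()

    def test_multiplicity_tally(self):
        df = survey_frame([srow(i, -2.5) for i in (1, 2, 3)])
        pairs = [mkpair(1, ring_type="TYR", n=1), mkpair(2, ring_type="TYR", n=1),
                 mkpair(3, ring_type="TYR", n=2)]
        table = pair_class_table(pairs, df)
        tyr_up = table[(table["ring_residue_type"] == "TYR")
                       & (table["z_class"] == "upfield")]
        assert dict(zip(tyr_up["n_restraints"], tyr_up["count"])) == {1: 2, 2: 1}

    def test_pair_without_survey_row_dropped(self, caplog):
        df = survey_frame([srow(1, 0.0)])
        with caplog.at_level("WARNING", logger="aroshift"):
            table = pair_class_table([mkpair(99)], df)
        assert table["count"].sum() == 0


class TestRestrainedVsZCohort:
    def test_outlier_amides_more_often_restrained(self, stats, tmp_path):
        """Restraints exist only near rings; ring-current shifts make the
        same amides outliers, so restrained proportion grows with |Z|."""
        from aroshift.synthetic import AmideTarget, SyntheticSpec, write_entry
        # one near-axial plant per ring (two such plants on one ring clash)
        close = {1: AmideTarget(30, 2.9, 0.0), 2: AmideTarget(32, 2.95, 10.0),
                 3: AmideTarget(34, 2.85, 5.0)}
        spec = SyntheticSpec(
            n_residues=40,
            aromatic_positions={30: "TRP", 32: "TRP", 34: "TRP"},
            amide_geometries=close, n_models=1,
            coordinate_jitter_A=0.0, shift_noise_ppm=0.05, seed=21,
        )
        paths = write_entry(spec, tmp_path, stats)
        ens = parse_structure(paths["structure"])
        df = build_survey(load_shifts(paths["shifts"]), ens, stats)
        records = filter_restraints(parse_restraints(paths["restraints"]))
        pairs = amide_aromatic_restraints(records, ens.residue_types())
        out = proportion_with_restraint_vs_z({"S": df}, {"S": pairs})
        by_bin = dict(zip(out["z_bin"], out["proportion"]))
        strong = [p for zb, p in by_bin.items() if zb <= -3]
        assert strong and min(strong) > by_bin[0]
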