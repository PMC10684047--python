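"""Editing filters on boundary fixtures and hand-traced contemporary-group
constructions."""

import numpy as np
import pandas as pd
import pytest

from mstnassoc.cohorts import (assign_calving_contemporary_groups,
                               assign_carcass_contemporary_groups,
                               edit_calving_records, edit_carcass_records)


def calving_frame(rows):
    base = {"calf": "c", "dam": "d", "sire": "s", "herd": "H1",
            "date": pd.Timestamp("2018-03-01"), "parity": 2, "age_days": 1100,
            "score": 1.0, "twin": False, "embryo_transfer": False,
            "breed_society": False, "genotyped_pair": True}
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec.update(r)
        rec["calf"] = f"c{i}"
        recs.append(rec)
    return pd.DataFrame(recs)


def varied_scores(n):
    return [{"score": float(1 + (i % 3))} for i in range(n)]


class TestCalvingEdits:
    def test_parity_boundary(self):
        df = calving_frame(varied_scores(6) + [{"parity": 15, "score": 2.0},
                                               {"parity": 16, "score": 3.0}])
        out, audits = edit_calving_records(df, parity_medians={1: 750, 2: 1100,
                                                               15: 5000, 16: 5400})
        assert audits[0].rule.startswith("parity")
        assert audits[0].n_removed == 1
        assert (out["parity"] <= 15).all()

    def test_first_parity_age_boundary(self):
        df = calving_frame(varied_scores(6)
                           + [{"parity": 1, "age_days": 659, "score": 2.0},
                              {"parity": 1, "age_days": 660, "score": 3.0}])
        med = {1: 700, 2: 1100}
        out, audits = edit_calving_records(df, parity_medians=med)
        ages = out.loc[out["parity"] == 1, "age_days"]
        assert 659 not in ages.values and 660 in ages.values

    def test_parity_median_deviation_boundary(self):
        med = {2: 1100}
        df = calving_frame(varied_scores(6)
                           + [{"age_days": 1100 + 425, "score": 2.0},
                              {"age_days": 1100 + 426, "score": 3.0}])
        out, audits = edit_calving_records(df, parity_medians=med)
        assert (1100 + 425) in out["age_days"].values
        assert (1100 + 426) not in out["age_days"].values

    def test_twin_et_sire_society_rules(self):
        df = calving_frame(varied_scores(6)
                           + [{"twin": True}, {"embryo_transfer": True},
                              {"sire": None}, {"breed_society": True}])
        out, audits = edit_calving_records(df, parity_medians={2: 1100})
        assert len(out) == 6
        removed = {a.rule: a.n_removed for a in audits}
        assert removed["twin birth or embryo transfer"] == 2
        assert removed["missing sire"] == 1
        assert removed["breed-society registered"] == 1

    def test_herd_year_without_variability_removed(self):
        flat = calving_frame([{"herd": "H2", "score": 1.0} for _ in range(5)])
        good = calving_frame(varied_scores(5))
        df = pd.concat([flat, good], ignore_index=True)
        out, audits = edit_calving_records(df, parity_medians={2: 1100})
        assert set(out["herd"]) == {"H1"}

    def test_few_genotyped_pairs_removed(self):
        few = calving_frame(varied_scores(6))
        few.loc[few.index[2:], "genotyped_pair"] = False  # only 2 genotyped
        many = calving_frame(varied_scores(6))
        many["herd"] = "H9"
        out, _ = edit_calving_records(pd.concat([few, many], ignore_index=True),
                                      parity_medians={2: 1100})
        assert set(out["herd"]) == {"H9"}

    def test_audit_conservation_and_order(self):
        df = calving_frame(varied_scores(8) + [{"parity": 16, "twin": True}])
        out, audits = edit_calving_records(df, parity_medians={2: 1100})
        for a in audits:
            assert a.n_in - a.n_removed == a.n_out
        for a, b in zip(audits, audits[1:]):
            assert a.n_out == b.n_in
        assert audits[-1].n_out == len(out)
        # the parity-16 twin is attributed to the first matching rule only
        assert audits[0].n_removed == 1
        assert audits[3].n_removed == 0

    def test_missing_required_field_named(self):
        df = calving_frame(varied_scores(3)).drop(columns="parity")
        with pytest.raises(KeyError, match="parity"):
            edit_calving_records(df)


def carcass_frame(rows):
    base = {"animal": "a", "herd": "H1", "slaughter_date": pd.Timestamp("2018-06-01"),
            "sex_class": "steer", "age_months": 24, "weight": 340.0,
            "dam_parity": 3, "embryo_transfer": False, "n_lifetime_herds": 1,
            "days_since_herd_move": np.nan, "breed_society": False}
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec.update(r)
        rec["animal"] = f"a{i}"
        recs.append(rec)
    return pd.DataFrame(recs)


class TestCarcassEdits:
    def test_sex_specific_age_windows(self):
        df = carcass_frame([
            {"sex_class": "steer", "age_months": 13},       # out
            {"sex_class": "steer", "age_months": 14},       # in
            {"sex_class": "steer", "age_months": 36},       # in
            {"sex_class": "steer", "age_months": 37},       # out
            {"sex_class": "young_bull", "age_months": 13},  # in
            {"sex_class": "young_bull", "age_months": 12},  # in
            {"sex_class": "young_bull", "age_months": 25},  # out
            {"sex_class": "heifer", "age_months": 14},      # in
        ])
        out, audits = edit_carcass_records(df)
        assert audits[0].n_removed == 3
        assert set(out["animal"]) == {"a1", "a2", "a4", "a5", "a7"}

    def test_weight_bounds_inclusive(self):
        df = carcass_frame([{"weight": 99.0}, {"weight": 100.0},
                            {"weight": 800.0}, {"weight": 801.0}])
        out, _ = edit_carcass_records(df)
        assert sorted(out["weight"]) == [100.0, 800.0]

    def test_dam_parity_and_residency(self):
        df = carcass_frame([
            {"dam_parity": 10}, {"dam_parity": 11},
            {"n_lifetime_herds": 2}, {"n_lifetime_herds": 3},
            {"days_since_herd_move": 100.0}, {"days_since_herd_move": 101.0},
        ])
        out, _ = edit_carcass_records(df)
        assert set(out["animal"]) == {"a0", "a2", "a5"}


def dated(herd, days, **kw):
    return [{"herd": herd, "date": pd.Timestamp("2018-01-01") + pd.Timedelta(days=d), **kw}
            for d in days]


class TestCalvingGroups:
    def test_consecutive_days_one_group(self):
        df = calving_frame(dated("H1", range(12)))
        cg, groups = assign_calving_contemporary_groups(df)
        assert len(groups) == 1 and len(groups[0]) == 12

    def test_chain_rule_boundary(self):
        # gap of exactly 10 d keeps the chain; 11 d breaks it
        df = calving_frame(dated("H1", list(range(10)) + [19] + [31]))
        cg, groups = assign_calving_contemporary_groups(df, min_cluster=1,
                                                        min_size=1)
        assert len(groups) == 2
        assert len(groups[0]) == 11

    def test_small_clusters_merge_within_span(self):
        # clusters of 4 and 6 separated by 30 d: merged span 40 d < 90
        df = calving_frame(dated("H1", [0, 1, 2, 3, 33, 34, 35, 36, 37, 38]))
        cg, groups = assign_calving_contemporary_groups(df)
        assert len(groups) == 1 and len(groups[0]) == 10
        assert groups[0].span_days == 38

    def test_merge_refused_beyond_span(self):
        # two clusters of 4, 100 d apart: no merge possible, both kept (>=3)
        df = calving_frame(dated("H1", [0, 1, 2, 3, 100, 101, 102, 103]))
        cg, groups = assign_calving_contemporary_groups(df)
        assert len(groups) == 2

    def test_residual_pair_discarded(self):
        df = calving_frame(dated("H1", [0, 1] + list(range(120, 130))))
        cg, groups = assign_calving_contemporary_groups(df)
        assert len(groups) == 1 and len(groups[0]) == 10
        assert cg.isna().sum() == 2

    def test_nearest_neighbour_merge_tie_to_earlier(self):
        # middle cluster of 3 equidistant (20 d) from both neighbours of 10
        days = (list(range(10)) + [29, 30, 31] + list(range(51, 61)))
        df = calving_frame(dated("H1", days))
        cg, groups = assign_calving_contemporary_groups(df)
        assert sorted(len(g) for g in groups) == [10, 13]
        assert len(groups[0]) == 13  # merged with the earlier neighbour

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(5)
        days = np.sort(rng.integers(0, 400, 80))
        df = calving_frame(dated("H1", days) + dated("H2", days[:40]))
        cg, groups = assign_calving_contemporary_groups(df)
        member = [i for g in groups for i in g.members]
        assert len(member) == len(set(member))
        assigned = cg.dropna()
        assert set(member) == set(assigned.index)
        # idempotence: each produced group re-clusters to itself
        for g in groups:
            cg2, groups2 = assign_calving_contemporary_groups(df.loc[g.members])
            assert len(groups2) == 1
            assert set(groups2[0].members) == set(g.members)


class TestCarcassGroups:
    def test_single_retained_group(self):
        df = carcass_frame([{"slaughter_date": pd.Timestamp("2018-06-01")
                             + pd.Timedelta(days=i * 10)} for i in range(6)])
        cg, groups = assign_carcass_contemporary_groups(
            df, genotyped=pd.Series(True, index=df.index))
        assert len(groups) == 1 and len(groups[0]) == 6

    def test_sex_split(self):
        rows = [{"sex_class": "steer"} for _ in range(5)] + \
               [{"sex_class": "heifer"} for _ in range(5)]
        df = carcass_frame(rows)
        cg, groups = assign_carcass_contemporary_groups(
            df, genotyped=pd.Series(True, index=df.index))
        assert len(groups) == 2
        assert {g.group_id.split(":")[1] for g in groups} == {"steer", "heifer"}

    def test_few_genotyped_dropped(self):
        df = carcass_frame([{} for _ in range(6)])
        genotyped = pd.Series([True] * 4 + [False] * 2, index=df.index)
        cg, groups = assign_carcass_contemporary_groups(df, genotyped)
        assert groups == []
        assert cg.isna().all()

    def test_sixty_day_chain_boundary(self):
        df = carcass_frame(
            [{"slaughter_date": pd.Timestamp("2018-01-01")} for _ in range(5)]
            + [{"slaughter_date": pd.Timestamp("2018-01-01")
                + pd.Timedelta(days=61 + i)} for i in range(5)])
        cg, groups = assign_carcass_contemporary_groups(
            df, genotyped=pd.Series(True, index=df.index))
        assert len(groups) == 2
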