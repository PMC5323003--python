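import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ehrkit as ek
from oracles import split_episodes


def episodes(df, patient, cols=("start", "end")):
    sub = df[df["id"] == patient]
    return list(zip(sub[cols[0]].tolist(), sub[cols[1]].tolist()))


class TestCutTvWorkedExample:
    """The five-patient follow-up table split every documented way."""

    def test_binary_chronic_two_drugs(self, tv_test):
        out = ek.cut_tv(tv_test, "start", "end", "drug_1", "id", "drug_1_state")
        out = ek.cut_tv(out, "start", "end", "drug_2", "id", "drug_2_state")
        assert episodes(out, 1) == [(0, 1000)]
        assert episodes(out, 2) == [(0, 233), (234, 689)]
        assert episodes(out, 3) == [(0, 553), (554, 1000)]
        assert episodes(out, 4) == [(0, 122), (123, 339), (340, 874)]
        # states: drug_2 switches on at its cut time
        p2 = out[out["id"] == 2]
        assert p2["drug_2_state"].tolist() == [0, 1]
        # the event indicator is replicated verbatim on both halves
        assert p2["event"].tolist() == [1, 1]
        p4 = out[out["id"] == 4]
        assert p4["drug_1_state"].tolist() == [0, 0, 1]
        assert p4["drug_2_state"].tolist() == [0, 1, 1]

    def test_start_stop_flip(self, tv_test):
        out = ek.cut_tv(tv_test, "start", "end", "drug_3_start", "id", "drug_3_state")
        out = ek.cut_tv(out, "start", "end", "drug_3_stop", "id", "drug_3_state")
        assert episodes(out, 1) == [(0, 109), (110, 399), (400, 1000)]
        assert episodes(out, 2) == [(0, 109), (110, 399), (400, 689)]
        assert out[out["id"] == 1]["drug_3_state"].tolist() == [0, 1, 0]

    def test_incremental_stages(self, tv_test):
        out = ek.cut_tv(tv_test, "start", "end", "stage_1", "id", "disease_stage",
                        on_existing="inc")
        out = ek.cut_tv(out, "start", "end", "stage_2", "id", "disease_stage",
                        on_existing="inc")
        assert episodes(out, 1) == [(0, 299), (300, 449), (450, 1000)]
        assert out[out["id"] == 1]["disease_stage"].tolist() == [0, 1, 2]
        # untouched patients keep a single all-zero episode
        assert episodes(out, 2) == [(0, 689)]
        assert out[out["id"] == 2]["disease_stage"].tolist() == [0]

    def test_chained_six_cuts(self, tv_test):
        out = tv_test
        for cut_var, name, mode in [
            ("drug_1", "drug_1_state", "flip"),
            ("drug_2", "drug_2_state", "flip"),
            ("drug_3_start", "drug_3_state", "flip"),
            ("drug_3_stop", "drug_3_state", "flip"),
            ("stage_1", "disease_stage", "inc"),
            ("stage_2", "disease_stage", "inc"),
        ]:
            out = ek.cut_tv(out, "start", "end", cut_var, "id", name, mode)
        assert episodes(out, 1) == [
            (0, 109), (110, 299), (300, 399), (400, 449), (450, 1000),
        ]

    def test_all_missing_cut_times_add_zero_state_only(self, tv_test):
        df = tv_test.assign(no_cut=np.nan)
        out = ek.cut_tv(df, "start", "end", "no_cut", "id", "no_cut_state")
        assert len(out) == len(tv_test)
        assert (out["no_cut_state"] == 0).all()
        pd.testing.assert_frame_equal(
            out.drop(columns="no_cut_state"),
            df.sort_values(["id", "start"]).reset_index(drop=True),
        )


class TestCutTvContracts:
    def test_cut_at_entry_updates_state_without_split(self):
        df = pd.DataFrame({"id": [1], "start": [0], "end": [100], "t": [0]})
        out = ek.cut_tv(df, "start", "end", "t", "id", "state")
        assert episodes(out, 1) == [(0, 100)]
        assert out["state"].tolist() == [1]

    def test_cut_at_exit_yields_single_day_episode(self):
        df = pd.DataFrame({"id": [1], "start": [0], "end": [100], "t": [100]})
        out = ek.cut_tv(df, "start", "end", "t", "id", "state")
        assert episodes(out, 1) == [(0, 99), (100, 100)]

    def test_tv_name_collision_rejected(self, tv_test):
        with pytest.raises(ValueError, match="collides"):
            ek.cut_tv(tv_test, "start", "end", "drug_1", "id", "start")

    def test_non_numeric_cut_var_rejected(self):
        df = pd.DataFrame({"id": [1], "start": [0], "end": [9], "t": ["x"]})
        with pytest.raises((ValueError, TypeError)):
            ek.cut_tv(df, "start", "end", "t", "id", "state")

    def test_unknown_on_existing_rejected(self, tv_test):
        with pytest.raises(ValueError, match="on_existing"):
            ek.cut_tv(tv_test, "start", "end", "drug_1", "id", "s", on_existing="bad")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        exit_=st.integers(1, 2000),
        t=st.one_of(st.none(), st.integers(-50, 2100)),
        state=st.integers(0, 3),
        mode=st.sampled_from(["flip", "inc"]),
    )
    def test_single_row_matches_oracle(self, exit_, t, state, mode):
        df = pd.DataFrame(
            {"id": [1], "start": [0], "end": [exit_], "t": [t], "state": [state]}
        )
        out = ek.cut_tv(df, "start", "end", "t", "id", "state", on_existing=mode)
        got = sorted(zip(out["start"], out["end"], out["state"]))
        want = split_episodes([(0, exit_, state)], [t], on_existing=mode)
        assert got == want

    def test_partition_and_replication_invariants_randomised(self, tv_test):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            base = pd.DataFrame(
                {
                    "id": range(1, n + 1),
                    "start": 0,
                    "end": rng.integers(50, 1500, size=n),
                    "payload": rng.integers(0, 10, size=n),
                }
            )
            df = base.copy()
            for j in range(int(rng.integers(1, 4))):
                cut = rng.integers(-100, 1600, size=n).astype(float)
                cut[rng.random(n) < 0.3] = np.nan
                df[f"c{j}"] = df["id"].map(dict(zip(base["id"], cut)))
                df = ek.cut_tv(df, "start", "end", f"c{j}", "id", f"s{j}")
            for pid, sub in df.groupby("id"):
                sub = sub.sort_values("start")
                orig = base[base["id"] == pid].iloc[0]
                # episodes tile [0, end] exactly: person-time conserved
                assert sub["start"].iloc[0] == 0
                assert sub["end"].iloc[-1] == orig["end"]
                assert (
                    sub["start"].iloc[1:].values == sub["end"].iloc[:-1].values + 1
                ).all()
                # non-constructed columns replicated verbatim
                assert (sub["payload"] == orig["payload"]).all()


class TestBuildCohort:
    @pytest.fixture
    def prevalence_like(self):
        def row(patid, year, event, crd, uts, tod, death, lcd, **extra):
            return dict(
                patid=patid, year=year, eventdate=event, crd=crd, uts=uts,
                tod=tod, deathdate=death, lcd=lcd,
                **extra,
            )

        dat = pd.DataFrame(
            [
                # registered long before cohort, never censored
                row(1, 2008, None, "2000-01-01", "1999-06-01", None, None, "2014-06-30"),
                # case diagnosed 2008-03-01
                row(2, 2008, "2008-03-01", "2001-01-01", "2000-01-01", None, None,
                    "2014-06-30"),
                # transferred out before cohort start: start > end, dropped
                row(3, 2008, None, "2000-01-01", "1999-06-01", "2005-12-01", None,
                    "2014-06-30"),
            ]
        )
        return ek.prev_terms(dat)

    def test_start_end_day_offsets(self, prevalence_like):
        cohort = ek.build_cohort(
            prevalence_like, "prev", "2006-01-01", "2012-12-31", diagnosis_start=None
        )
        p1 = cohort[cohort["patid"] == 1].iloc[0]
        assert p1["start"] == 0
        assert p1["end"] == (pd.Timestamp("2012-12-31") - pd.Timestamp("2006-01-01")).days

    def test_pre_cohort_transfer_out_dropped(self, prevalence_like):
        cohort = ek.build_cohort(
            prevalence_like, "prev", "2006-01-01", "2012-12-31", diagnosis_start=None
        )
        assert 3 not in set(cohort["patid"])

    def test_diagnosis_date_enters_start_for_cases(self, prevalence_like):
        cohort = ek.build_cohort(
            prevalence_like, "prev", "2006-01-01", "2012-12-31",
            diagnosis_start="eventdate",
        )
        p2 = cohort[cohort["patid"] == 2].iloc[0]
        assert p2["case"] == 1
        assert p2["start_date"] == pd.Timestamp("2008-03-01")
        p1 = cohort[cohort["patid"] == 1].iloc[0]
        assert p1["case"] == 0
        assert p1["start_date"] == pd.Timestamp("2006-01-01")

    def test_one_row_per_patient(self, prevalence_like):
        doubled = pd.concat(
            [prevalence_like, prevalence_like.assign(year=2009)], ignore_index=True
        )
        doubled = ek.prev_terms(doubled.drop(
            columns=[c for c in doubled.columns if c.endswith(("numerator", "denominator"))
                     or c in ("followup", "year_start", "year_end")]
        ))
        cohort = ek.build_cohort(doubled, "prev", "2006-01-01", "2012-12-31", None)
        assert cohort["patid"].is_unique

    def test_unknown_cohort_type_rejected(self, prevalence_like):
        with pytest.raises(ValueError, match="cohort_type"):
            ek.build_cohort(prevalence_like, "bogus", "2006-01-01", "2012-12-31")

    def test_missing_criteria_columns_named(self, prevalence_like):
        broken = prevalence_like.drop(columns=["uts", "lcd"])
        with pytest.raises(ValueError, match="uts"):
            ek.build_cohort(broken, "prev", "2006-01-01", "2012-12-31")

    def test_start_le_end_invariant(self, db_path):
        # full pipeline cohort: every retained row satisfies start <= end
        codes = [273, 277, 293, 351, 257]
        with ek.Database(db_path) as db:
            reg = ek.select_by_year(
                db, "Patient",
                ["patid", "practid", "gender", "yob", "crd", "tod", "deathdate"],
                "crd < STARTDATE", year_range=range(2008, 2013),
            )
            inc = ek.select_by_year(
                db, ["Clinical", "Referral"], ["patid", "eventdate", "medcode"],
                "medcode %in% .(codes) & eventdate <= ENDDATE",
                year_range=range(2008, 2013), selector_fn=ek.first_events,
                env={"codes": codes},
            )
            practices = ek.select_events(db, "Practice")
        inc = inc.sort_values("eventdate").drop_duplicates(["patid", "year"])
        dat = reg.merge(inc[["patid", "year", "eventdate"]], on=["patid", "year"],
                        how="left")
        dat = ek.prev_terms(dat).merge(practices, on="practid", how="left")
        cohort = ek.build_cohort(dat, "prev", "2006-01-01", "2012-12-31", "eventdate")
        assert (cohort["start"] <= cohort["end"]).all()
        assert cohort["patid"].is_unique
        assert set(cohort["case"]) <= {0, 1}
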