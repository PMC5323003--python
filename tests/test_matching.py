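import numpy as np
import pandas as pd
import pytest

import ehrkit as ek


def make_pool(n, rng, practices=(1, 2, 3)):
    return pd.DataFrame(
        {
            "patid": np.arange(1, n + 1) * 1000 + rng.choice(practices, size=n),
            "practid": rng.choice(practices, size=n),
            "gender": rng.choice([0, 1], size=n),
            "region": rng.choice([1, 2], size=n),
            "yob": rng.integers(1940, 1990, size=n),
            "eventdate": [None] * n,
        }
    )


@pytest.fixture
def cases():
    return pd.DataFrame(
        {
            "patid": [11, 22, 33],
            "practid": [1, 2, 3],
            "gender": [0, 1, 0],
            "region": [1, 1, 2],
            "yob": [1950, 1960, 1970],
            "eventdate": ["2008-01-01", "2009-06-01", "2010-03-01"],
        }
    )


class TestGetMatches:
    def test_full_ratio_when_pool_is_rich(self, cases):
        rng = np.random.default_rng(0)
        pool = make_pool(400, rng)
        m = ek.get_matches(cases, pool, ["gender", "region"], n_controls=4, seed=1)
        assert m.groupby("case_id").size().eq(4).all()
        assert len(m) == 4 * len(cases)

    def test_matched_controls_share_match_vars(self, cases):
        rng = np.random.default_rng(0)
        pool = make_pool(400, rng)
        m = ek.get_matches(cases, pool, ["gender", "region"], n_controls=4, seed=1)
        lookup = cases.set_index("patid")
        for row in m.itertuples():
            assert row.gender == lookup.loc[row.case_id, "gender"]
            assert row.region == lookup.loc[row.case_id, "region"]

    def test_incidence_density_reuses_controls(self):
        # two identical cases, exactly 4 eligible controls: IDM gives both
        # cases the full set, so every control is used twice
        cases = pd.DataFrame(
            {"patid": [1, 2], "gender": [0, 0], "eventdate": ["2008-01-01"] * 2}
        )
        pool = pd.DataFrame(
            {"patid": [10, 11, 12, 13], "gender": [0] * 4, "eventdate": [None] * 4}
        )
        m = ek.get_matches(cases, pool, ["gender"], n_controls=4,
                           method="incidence_density", seed=5)
        assert len(m) == 8
        assert m["patid"].value_counts().eq(2).all()

    def test_incidence_density_requires_diagnosis_free_at_case_date(self):
        cases = pd.DataFrame({"patid": [1], "gender": [0], "eventdate": ["2008-06-01"]})
        pool = pd.DataFrame(
            {
                "patid": [10, 11, 12],
                "gender": [0, 0, 0],
                # diagnosed before, exactly at, and after the case's date
                "eventdate": ["2008-01-01", "2008-06-01", "2009-01-01"],
            }
        )
        m = ek.get_matches(cases, pool, ["gender"], n_controls=4, seed=1)
        assert set(m["patid"]) == {12}

    def test_exact_matching_depletes_pool(self):
        cases = pd.DataFrame(
            {"patid": [1, 2], "gender": [0, 0], "eventdate": [None, None]}
        )
        pool = pd.DataFrame({"patid": range(10, 15), "gender": [0] * 5,
                             "eventdate": [None] * 5})
        m = ek.get_matches(cases, pool, ["gender"], n_controls=4, method="exact",
                           seed=2)
        sizes = m.groupby("case_index").size()
        assert sizes.loc[0] == 4 and sizes.loc[1] == 1
        assert not m["patid"].duplicated().any()

    def test_empty_pool_returns_empty_without_error(self, cases):
        m = ek.get_matches(cases, cases.iloc[0:0], ["gender"], n_controls=4, seed=1)
        assert m.empty
        assert "case_id" in m.columns

    def test_extra_conditions_bound_birth_year(self, cases):
        rng = np.random.default_rng(0)
        pool = make_pool(600, rng)
        m = ek.get_matches(
            cases, pool, ["gender"], n_controls=4, seed=3,
            extra_conditions="yob >= (.(CASE$yob)-2) & yob <= (.(CASE$yob)+2)",
        )
        lookup = cases.set_index("patid")["yob"]
        assert len(m) > 0
        assert all(abs(r.yob - lookup.loc[r.case_id]) <= 2 for r in m.itertuples())

    def test_unresolvable_extra_condition_names_slot(self, cases):
        rng = np.random.default_rng(0)
        pool = make_pool(50, rng)
        with pytest.raises(KeyError, match="nope"):
            ek.get_matches(cases, pool, ["gender"], seed=1,
                           extra_conditions="yob >= .(CASE$nope)")

    def test_unknown_method_rejected(self, cases):
        with pytest.raises(ValueError, match="method"):
            ek.get_matches(cases, cases, ["gender"], method="propensity")

    def test_fixed_seed_reproduces_matches(self, cases):
        rng = np.random.default_rng(0)
        pool = make_pool(400, rng)
        a = ek.get_matches(cases, pool, ["gender"], n_controls=4, seed=9)
        b = ek.get_matches(cases, pool, ["gender"], n_controls=4, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = ek.get_matches(cases, pool, ["gender"], n_controls=4, seed=10)
        assert not a.equals(c)


class TestMatchOnIndex:
    def write_consults(self, path, practid, rows):
        df = pd.DataFrame(rows, columns=["patid", "eventdate"])
        df.to_csv(path / f"Consultation_{practid}.csv", index=False)

    def test_boundary_consultation_is_eligible(self, tmp_path):
        cases = pd.DataFrame(
            {"patid": [11], "practid": [1], "gender": [0],
             "eventdate": ["2008-06-01"]}
        )
        pool = pd.DataFrame(
            {"patid": [21], "practid": [1], "gender": [0], "eventdate": [None]}
        )
        # consultation exactly 90 days after the index date: inclusive bound
        self.write_consults(tmp_path, 1, [(21, "2008-08-30")])
        m = ek.match_on_index(cases, pool, "eventdate", ["gender"], tmp_path,
                              index_diff_limit=90, seed=1)
        assert len(m) == 1
        assert m["dummy_index"].iloc[0] == "2008-08-30"

    def test_just_outside_limit_is_ineligible(self, tmp_path):
        cases = pd.DataFrame(
            {"patid": [11], "practid": [1], "gender": [0],
             "eventdate": ["2008-06-01"]}
        )
        pool = pd.DataFrame(
            {"patid": [21], "practid": [1], "gender": [0], "eventdate": [None]}
        )
        self.write_consults(tmp_path, 1, [(21, "2008-08-31")])  # 91 days away
        m = ek.match_on_index(cases, pool, "eventdate", ["gender"], tmp_path,
                              index_diff_limit=90, seed=1)
        assert m.empty

    def test_same_practice_required(self, tmp_path):
        cases = pd.DataFrame(
            {"patid": [11], "practid": [1], "gender": [0],
             "eventdate": ["2008-06-01"]}
        )
        pool = pd.DataFrame(
            {"patid": [21], "practid": [2], "gender": [0], "eventdate": [None]}
        )
        self.write_consults(tmp_path, 1, [(21, "2008-06-01")])
        self.write_consults(tmp_path, 2, [(21, "2008-06-01")])
        m = ek.match_on_index(cases, pool, "eventdate", ["gender"], tmp_path,
                              index_diff_limit=9999, seed=1)
        assert m.empty  # control is in practice 2, case in practice 1

    def test_huge_limit_reduces_to_practice_matching(self, tmp_path):
        rng = np.random.default_rng(4)
        cases = pd.DataFrame(
            {"patid": [11], "practid": [1], "gender": [0],
             "eventdate": ["2008-06-01"]}
        )
        pool = pd.DataFrame(
            {
                "patid": [21, 22, 23],
                "practid": [1, 1, 1],
                "gender": [0, 0, 1],
                "eventdate": [None] * 3,
            }
        )
        self.write_consults(
            tmp_path, 1, [(21, "1999-01-01"), (22, "2013-12-01"), (23, "2008-06-01")]
        )
        m = ek.match_on_index(cases, pool, "eventdate", ["gender"], tmp_path,
                              index_diff_limit=10**6, seed=1)
        # gender-matched practice members qualify regardless of distance
        assert set(m["patid"]) == {21, 22}

    def test_missing_practice_file_warns_and_skips(self, tmp_path):
        cases = pd.DataFrame(
            {"patid": [11, 12], "practid": [1, 2], "gender": [0, 0],
             "eventdate": ["2008-06-01", "2008-06-01"]}
        )
        pool = pd.DataFrame(
            {"patid": [21, 22], "practid": [1, 2], "gender": [0, 0],
             "eventdate": [None, None]}
        )
        self.write_consults(tmp_path, 1, [(21, "2008-06-10")])
        with pytest.warns(UserWarning, match="practice 2"):
            m = ek.match_on_index(cases, pool, "eventdate", ["gender"], tmp_path,
                                  index_diff_limit=90, seed=1)
        assert set(m["case_id"]) == {11}

    def test_closest_consultation_becomes_dummy_index(self, tmp_path):
        cases = pd.DataFrame(
            {"patid": [11], "practid": [1], "gender": [0],
             "eventdate": ["2008-06-01"]}
        )
        pool = pd.DataFrame(
            {"patid": [21], "practid": [1], "gender": [0], "eventdate": [None]}
        )
        self.write_consults(
            tmp_path, 1,
            [(21, "2008-05-25"), (21, "2008-06-03"), (21, "2008-08-01")],
        )
        m = ek.match_on_index(cases, pool, "eventdate", ["gender"], tmp_path,
                              index_diff_limit=90, seed=1)
        assert m["dummy_index"].iloc[0] == "2008-06-03"
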