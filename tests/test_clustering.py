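"""Snapshots, MCA embedding, k-means selection and transition tables."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from morbtraj import (
    build_snapshots,
    kmeans_select,
    mca_embed,
    normalize_records,
    stack_snapshots,
    tabulate_transitions,
)
from morbtraj.clustering import DIED, NO_FOLLOWUP, PRESENT, Snapshot


@pytest.fixture()
def three_patient_cohort(catalog):
    """Hand-built fixture: p1 accrues early, p2 spreads out, p3 dies mid-way."""
    raw = pd.DataFrame(
        [
            ("p1", "female", "I10", "2000-01-01"),
            ("p1", "female", "E10", "2000-01-05"),
            ("p2", "female", "I10", "2000-01-01"),
            ("p2", "female", "J45", "2001-01-01"),
            ("p2", "female", "K21", "2002-01-01"),
            ("p3", "female", "I10", "2000-01-01"),
            ("p3", "female", "E10", "2000-06-01"),
        ],
        columns=["patient_id", "sex", "icd10_code", "diagnosis_date"],
    )
    meta = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3"],
            "sex": ["female"] * 3,
            "age_at_assessment": [50, 55, 60],
            "assessment_date": ["2000-01-01"] * 3,
            "death_date": [pd.NaT, pd.NaT, "2000-12-01"],  # p3 dies at day 335
            "followup_end": ["2005-01-01", "2005-01-01", "2000-12-01"],
        }
    )
    return normalize_records(raw, catalog, tie_seed=0, meta=meta)


class TestSnapshots:
    def test_manual_tabulation(self, three_patient_cohort):
        snaps = build_snapshots(three_patient_cohort, [200, 500, 1000])
        # t0: everyone present; accrued = first-day diagnoses only
        t0 = snaps[0]
        assert set(t0.matrix.index) == {"p1", "p2", "p3"}
        assert t0.matrix.loc["p1", "I10-I15"] == 1
        assert t0.matrix.loc["p1", "E10-E14"] == 0  # accrues only at day 4
        assert t0.t_days == 0
        # by t=200 p1 has both blocks and p2 still only its first
        t1 = snaps[1]
        assert t1.matrix.loc["p1", "E10-E14"] == 1
        assert t1.matrix.loc["p2", "J40-J47"] == 0

    def test_accrual_is_monotone_and_death_absorbs(self, three_patient_cohort):
        snaps = build_snapshots(three_patient_cohort, [200, 500, 1000])
        # p3 died at day 335: present at t=200, absorbed from t=500 on
        assert snaps[1].status.loc["p3"] == PRESENT
        assert snaps[2].status.loc["p3"] == DIED
        assert "p3" not in snaps[2].matrix.index
        # monotone accrual for surviving patients
        for a, b in zip(snaps, snaps[1:]):
            shared = a.matrix.index.intersection(b.matrix.index)
            assert (b.matrix.loc[shared] >= a.matrix.loc[shared]).all().all()

    def test_patient_complete_before_first_threshold_has_constant_rows(self, three_patient_cohort):
        snaps = build_snapshots(three_patient_cohort, [200, 500, 1000])
        rows = [s.matrix.loc["p1"] for s in snaps[1:]]
        for r in rows[1:]:
            pd.testing.assert_series_equal(r, rows[0])

    def test_requires_multimorbid(self, catalog):
        raw = pd.DataFrame(
            [("a", "female", "I10", "2000-01-01")],
            columns=["patient_id", "sex", "icd10_code", "diagnosis_date"],
        )
        cohort = normalize_records(raw, catalog, tie_seed=0)
        with pytest.raises(ValueError):
            build_snapshots(cohort, [100])


def ca_oracle_row_coords(X):
    """Independent correspondence-analysis oracle: eigendecomposition route
    (no SVD of the standardised residual matrix)."""
    Z = np.hstack([X, 1.0 - X])
    P = Z / Z.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    # row-profile chi-square inner product matrix
    Dc_inv = np.diag(1.0 / c)
    profiles = P / r[:, None]
    centred = profiles - c
    # weighted Gram matrix of centred profiles in chi-square metric
    G = centred @ Dc_inv @ centred.T * np.sqrt(np.outer(r, r))
    w, vec = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, vec = w[order], vec[:, order]
    keep = w > 1e-12
    coords = vec[:, keep] * np.sqrt(w[keep]) / np.sqrt(r)[:, None]
    return coords, w[keep]


class TestMCA:
    def _matrix(self):
        rng = np.random.default_rng(0)
        X = (rng.random((12, 4)) < 0.5).astype(float)
        X[0] = X[1]  # duplicated profile
        return pd.DataFrame(X, columns=list("abcd"))

    def test_duplicate_rows_coincide(self):
        m = self._matrix()
        res = mca_embed(m)
        np.testing.assert_allclose(
            res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[1].to_numpy(), atol=1e-9
        )

    def test_matches_eigendecomposition_oracle_up_to_sign(self):
        m = self._matrix()
        res = mca_embed(m)
        oracle, w = ca_oracle_row_coords(m.to_numpy())
        assert res.eigenvalues == pytest.approx(w, abs=1e-9)
        k = min(res.coordinates.shape[1], oracle.shape[1])
        for j in range(k):
            ours, theirs = res.coordinates.iloc[:, j].to_numpy(), oracle[:, j]
            agree = np.allclose(ours, theirs, atol=1e-6) or np.allclose(ours, -theirs, atol=1e-6)
            assert agree, f"axis {j} mismatch"

    def test_total_inertia_identity(self):
        # binary MCA: total inertia = categories/variables - 1 = 1
        res = mca_embed(self._matrix())
        assert res.eigenvalues.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.explained_inertia.sum() == pytest.approx(1.0)

    def test_constant_column_dropped_and_clamp_warns(self):
        m = self._matrix()
        m["e"] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            res = mca_embed(m, n_components=50)
        assert res.dropped_columns == ["e"]


class TestKMeans:
    def test_separated_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(8, 0.2, (30, 2))])
        coords = pd.DataFrame(pts, columns=["dim1", "dim2"])
        model = kmeans_select(coords, k_grid=[2], k_final=2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_score(truth, model.assignments.to_numpy()) == 1.0

    def test_ch_score_matches_hand_formula(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]])
        coords = pd.DataFrame(pts, columns=["dim1", "dim2"])
        model = kmeans_select(coords, k_grid=[2], k_final=2, seed=0)
        labels = model.assignments.to_numpy()
        # CH = (B/(k-1)) / (W/(n-k)), computed from first principles
        n, k = len(pts), 2
        overall = pts.mean(axis=0)
        B = W = 0.0
        for c in np.unique(labels):
            grp = pts[labels == c]
            B += len(grp) * ((grp.mean(axis=0) - overall) ** 2).sum()
            W += ((grp - grp.mean(axis=0)) ** 2).sum()
        expected = (B / (k - 1)) / (W / (n - k))
        got = model.diagnostics.set_index("k").loc[2, "calinski_harabasz"]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_same_seed_identical_assignments(self):
        rng = np.random.default_rng(2)
        coords = pd.DataFrame(rng.normal(size=(50, 3)), columns=["dim1", "dim2", "dim3"])
        m1 = kmeans_select(coords, k_grid=[4], k_final=4, seed=7)
        m2 = kmeans_select(coords, k_grid=[4], k_final=4, seed=7)
        assert (m1.assignments == m2.assignments).all()

    def test_k_larger_than_points_errors(self):
        coords = pd.DataFrame(np.eye(3), columns=["dim1", "dim2", "dim3"])
        with pytest.raises(ValueError):
            kmeans_select(coords, k_grid=[5], k_final=5)


def _snapshot(label, t, status, matrix_index):
    idx = pd.Index(list(status), name="patient_id")
    status_s = pd.Series(list(status.values()), index=idx)
    mat = pd.DataFrame(
        0, index=[p for p in idx if status[p] == PRESENT], columns=["x"], dtype=np.int8
    )
    return Snapshot(label=label, t_days=t, matrix=mat, status=status_s)


class TestTransitions:
    def test_scripted_fixture(self):
        snaps = [
            _snapshot("t0", 0, {"a": PRESENT, "b": PRESENT, "c": PRESENT}, None),
            _snapshot("t1", 10, {"a": PRESENT, "b": PRESENT, "c": DIED}, None),
            _snapshot("t2", 20, {"a": PRESENT, "b": NO_FOLLOWUP, "c": DIED}, None),
        ]
        idx = pd.MultiIndex.from_tuples(
            [("t0", "a"), ("t0", "b"), ("t0", "c"), ("t1", "a"), ("t1", "b"), ("t2", "a")],
            names=["timepoint", "patient_id"],
        )
        assignments = pd.Series([1, 1, 2, 1, 2, 1], index=idx)
        flows = tabulate_transitions(assignments, snaps).set_index(["source", "target"])["value"]
        assert flows.loc[("t0:c1", "t1:c1")] == 1  # a stays
        assert flows.loc[("t0:c1", "t1:c2")] == 1  # b moves
        assert flows.loc[("t0:c2", "t1:died")] == 1  # c dies
        assert flows.loc[("t1:c2", "t2:no_followup")] == 1
        assert flows.loc[("t1:died", "t2:died")] == 1  # absorbing self-flow

    def test_conservation(self, planted_cohort):
        from morbtraj import cumulative_diagnosis_quantiles

        cohort, _ = planted_cohort
        sub = cohort.by_sex("female")
        q = cumulative_diagnosis_quantiles(sub).tolist()
        snaps = build_snapshots(sub, q)
        stacked = stack_snapshots(snaps).fillna(0).astype(np.int8)
        emb = mca_embed(stacked, n_components=3)
        model = kmeans_select(emb.coordinates, k_grid=[3], k_final=3, seed=1)
        flows = tabulate_transitions(model.assignments, snaps)
        out0 = flows[flows["source"].str.startswith("t0:")]["value"].sum()
        n_multimorbid = len(snaps[0].matrix)
        assert out0 == n_multimorbid
        # occupancy at t1 equals inflow into t1 states and outflow from them
        inflow = flows[flows["target"].str.startswith("t1:")].groupby("target")["value"].sum()
        outflow = flows[flows["source"].str.startswith("t1:")].groupby("source")["value"].sum()
        for state, v in inflow.items():
            assert outflow.loc[state.replace("t1:", "t1:", 1)] == v
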