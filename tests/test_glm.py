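"""Vertex-wise GLM, FDR thresholding and cluster summaries."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from gwrkit.glm import (
    DesignError,
    DesignSpec,
    fdr_threshold,
    fit_vertex_glm,
    summarize_clusters,
)
from gwrkit.mesh import VertexMap
from gwrkit.phantom import icosphere
from gwrkit.records import SubjectRecord


def make_subjects(rng, n_per_group=18, n_vertices=20, maps=("y",), nuisance=True):
    subjects = []
    for g, group in ((1, "patient"), (0, "control")):
        for i in range(n_per_group):
            covs = {}
            if nuisance:
                covs = {
                    "age": float(rng.normal(49, 9)),
                    "education": float(rng.normal(13, 2)),
                    "dosage": float(rng.normal(660, 400)) if g else np.nan,
                    "duration": float(rng.normal(25, 9)) if g else np.nan,
                    "symptom_severity": float(rng.normal(40, 10)) if g else np.nan,
                }
            rec = SubjectRecord(subject_id=f"{group}{i}", group=group, covariates=covs)
            for name in maps:
                rec.maps[name] = VertexMap(rng.normal(size=n_vertices))
            subjects.append(rec)
    return subjects


def oracle_ols(y, x, g_col):
    """Brute-force normal-equations OLS via pseudo-inverse."""
    beta = np.linalg.pinv(x) @ y
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(cov[g_col, g_col])
    return beta[g_col], se, beta[g_col] / se, df


class TestVertexGlm:
    def test_identical_groups_give_zero_effect(self, rng):
        subjects = make_subjects(rng, n_per_group=5, nuisance=False)
        shared = rng.normal(size=20)
        for s in subjects:
            s.maps["y"] = VertexMap(shared.copy())
        res = fit_vertex_glm(subjects, DesignSpec(outcome="y", nuisance=()))
        assert np.allclose(res.beta_group.values, 0.0)
        assert np.allclose(res.t_stat.values, 0.0)

    def test_matches_normal_equations_oracle(self, rng):
        """20-vertex, 36-subject instance with nuisance covariates and a
        per-vertex regressor: betas/SEs/t to 1e-8 against the pinv oracle."""
        subjects = make_subjects(rng, n_per_group=18, maps=("y", "r"))
        design = DesignSpec(outcome="y", pervertex_regressors=("r",))
        res = fit_vertex_glm(subjects, design)
        groups = np.array([1.0 if s.group == "patient" else 0.0 for s in subjects])

        def col(name):
            v = np.array([s.covariates[name] for s in subjects])
            if name in ("dosage", "duration", "symptom_severity"):
                out = np.zeros_like(v)
                pat = groups == 1
                out[pat] = v[pat] - v[pat].mean()
                return out
            return v - v.mean()

        for v in range(20):
            y = np.array([s.maps["y"].values[v] for s in subjects])
            r = np.array([s.maps["r"].values[v] for s in subjects])
            x = np.column_stack(
                [np.ones(36), groups]
                + [col(n) for n in ("age", "education", "dosage", "duration", "symptom_severity")]
                + [r - r.mean()]
            )
            b, se, t, df = oracle_ols(y, x, 1)
            assert res.beta_group.values[v] == pytest.approx(b, abs=1e-8)
            assert res.t_stat.values[v] == pytest.approx(t, abs=1e-8)
            assert res.df[v] == df

    def test_orthogonal_pervertex_regressor_leaves_group_beta(self, rng):
        """A per-vertex regressor orthogonal to every design column cannot
        move the group coefficient."""
        subjects = make_subjects(rng, n_per_group=10, nuisance=False, maps=("y",))
        groups = np.array([1.0 if s.group == "patient" else 0.0 for s in subjects])
        x = np.column_stack([np.ones(20), groups])
        proj = np.eye(20) - x @ np.linalg.pinv(x)
        r = proj @ rng.normal(size=20)  # orthogonal to intercept and group
        for s_idx, s in enumerate(subjects):
            s.maps["r"] = VertexMap(np.full(20, r[s_idx]))
        base = fit_vertex_glm(subjects, DesignSpec(outcome="y", nuisance=()))
        with_r = fit_vertex_glm(
            subjects, DesignSpec(outcome="y", nuisance=(), pervertex_regressors=("r",))
        )
        assert np.abs(base.beta_group.values - with_r.beta_group.values).max() < 1e-10

    def test_rank_deficient_global_design_raises(self, rng):
        subjects = make_subjects(rng, n_per_group=5)
        for s in subjects:
            s.covariates["education"] = s.covariates["age"]  # collinear
        with pytest.raises(DesignError, match="rank deficient"):
            fit_vertex_glm(subjects, DesignSpec(outcome="y", nuisance=("age", "education")))

    def test_listwise_deletion_per_vertex(self, rng):
        subjects = make_subjects(rng, n_per_group=6, nuisance=False)
        subjects[0].maps["y"].values[3] = np.nan
        subjects[0].maps["y"].missing[3] = True
        res = fit_vertex_glm(subjects, DesignSpec(outcome="y", nuisance=()))
        assert res.n_used[3] == 11 and res.n_used[0] == 12
        # oracle on the reduced subject set
        y = np.array([s.maps["y"].values[3] for s in subjects[1:]])
        g = np.array([1.0 if s.group == "patient" else 0.0 for s in subjects[1:]])
        b, se, t, df = oracle_ols(y, np.column_stack([np.ones(11), g]), 1)
        assert res.beta_group.values[3] == pytest.approx(b, abs=1e-10)
        assert res.df[3] == df

    def test_insufficient_df_vertex_is_missing(self, rng):
        subjects = make_subjects(rng, n_per_group=2, nuisance=False, n_vertices=4)
        for s in subjects[:3]:
            s.maps["y"].values[0] = np.nan
            s.maps["y"].missing[0] = True
        res = fit_vertex_glm(subjects, DesignSpec(outcome="y", nuisance=()))
        assert res.p_value.missing[0]
        assert not res.p_value.missing[1]

    def test_needs_both_groups(self, rng):
        subjects = make_subjects(rng, n_per_group=4, nuisance=False)
        for s in subjects:
            s.group = "patient"
        with pytest.raises(DesignError, match="both groups"):
            fit_vertex_glm(subjects, DesignSpec(outcome="y", nuisance=()))


def brute_force_bh(p, q):
    """Oracle: enumerate every threshold candidate."""
    p = np.sort(np.asarray(p))
    m = len(p)
    thr = 0.0
    for i, pi in enumerate(p, start=1):
        if pi <= i * q / m:
            thr = pi
    return thr


class TestFdr:
    def test_all_ones_give_empty_mask(self):
        thr, sig = fdr_threshold(VertexMap(np.ones(50)), 0.05)
        assert thr == 0.0 and not sig.any()

    def test_enumerable_example(self):
        thr, sig = fdr_threshold(VertexMap(np.array([0.001, 0.01, 0.02, 0.5])), 0.05)
        assert thr == pytest.approx(0.02)
        assert sig.tolist() == [True, True, True, False]

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            p = rng.uniform(size=100) ** 2
            thr, sig = fdr_threshold(VertexMap(p), 0.05)
            assert thr == pytest.approx(brute_force_bh(p, 0.05))
            assert sig.sum() == (p <= thr).sum() if thr > 0 else sig.sum() == 0

    def test_matches_statsmodels_rejections(self, rng):
        p = rng.uniform(size=500) ** 3
        _, sig = fdr_threshold(VertexMap(p), 0.05)
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(sig, reject)

    def test_missing_excluded_from_family(self):
        p = np.array([0.001, np.nan, 0.04, np.nan])
        thr, sig = fdr_threshold(VertexMap(p), 0.05)
        # m = 2: 0.001 <= 0.025 passes, 0.04 > 0.05 fails at i=2? 0.04 <= 0.05 passes
        assert sig.tolist() == [True, False, True, False]


class TestClusters:
    def test_empty_mask(self, ico1):
        rep = summarize_clusters(np.zeros(ico1.n_vertices, dtype=bool), ico1)
        assert rep.n_significant == 0 and rep.n_components == 0

    def test_mask_equal_to_patch(self, ico3_r30):
        from gwrkit.mesh import geodesic_distances

        patch = geodesic_distances(ico3_r30, 0) <= 10.0
        rep = summarize_clusters(patch, ico3_r30, patch)
        assert rep.dice == 1.0 and rep.n_components == 1
        assert rep.n_in_patch == patch.sum() and rep.n_out_patch == 0

    def test_matches_flood_fill_oracle(self, ico3_r30, rng):
        from gwrkit.mesh import vertex_adjacency

        mask = rng.uniform(size=ico3_r30.n_vertices) < 0.2
        rep = summarize_clusters(mask, ico3_r30)
        adj = vertex_adjacency(ico3_r30)
        seen = np.zeros(len(mask), dtype=bool)
        comps = []
        for v in np.flatnonzero(mask):
            if seen[v]:
                continue
            stack, comp = [v], set()
            seen[v] = True
            while stack:
                u = stack.pop()
                comp.add(u)
                for w in adj[u]:
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            comps.append(comp)
        assert rep.n_components == len(comps)
        assert rep.largest_component == max(len(c) for c in comps)
        # identical partition: two vertices share a label iff one flood-fill component
        labels = rep.component_labels
        for comp in comps:
            assert len({labels[v] for v in comp}) == 1
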