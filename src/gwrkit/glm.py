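"""Vertex-wise group statistics: per-vertex general linear models with
global nuisance covariates and per-vertex regressors, Benjamini-Hochberg
FDR thresholding, and cluster summaries.

At each vertex v the outcome y_s(v) across subjects s is regressed on
[1, group_s, nuisance_s ..., r_s(v) ...] by ordinary least squares, where
r are per-vertex regressors (e.g. cortical thickness) demeaned across
subjects at that vertex.  The group coefficient's two-sided t test gives
the statistic map; pooling all non-missing vertices, the step-up
Benjamini-Hochberg procedure at q (default 0.05) yields the significance
threshold.  Including a per-vertex regressor tests the group effect while
controlling for that local measure — e.g. whether a contrast difference
survives controlling for thickness at each vertex.

Covariates that exist only for patients (antipsychotic dosage, illness
duration, symptom severity) are entered as patient-deviation regressors:
deviation from the patient mean for patients, 0 for controls.  Raw
inclusion would be undefined for controls; the deviation coding keeps the
column orthogonal to the group indicator in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .mesh import TriangleMesh, VertexMap, adjacency_matrix
from .records import SubjectRecord

__all__ = [
    "DesignSpec",
    "GlmResult",
    "ClusterReport",
    "fit_vertex_glm",
    "fdr_threshold",
    "summarize_clusters",
]

PATIENT_ONLY = ("dosage", "duration", "symptom_severity")
DEFAULT_NUISANCE = ("age", "education", "dosage", "duration", "symptom_severity")


class DesignError(ValueError):
    """Raised for unusable designs (rank deficiency, bad configuration)."""


@dataclass(frozen=True)
class DesignSpec:
    """What to test: outcome map, nuisance set, per-vertex regressors, q.

    ``outcome`` names a map every subject carries (e.g. 'gwr', 'thickness').
    ``pervertex_regressors`` name further subject maps entered per vertex.
    """

    outcome: str
    nuisance: tuple[str, ...] = DEFAULT_NUISANCE
    pervertex_regressors: tuple[str, ...] = ()
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise DesignError("fdr_q must be in (0, 1)")
        if self.outcome in self.pervertex_regressors:
            raise DesignError("outcome cannot also be a per-vertex regressor")


@dataclass
class GlmResult:
    """Per-vertex GLM output for the group contrast (patient - control)."""

    beta_group: VertexMap
    t_stat: VertexMap
    p_value: VertexMap
    df: np.ndarray
    n_used: np.ndarray
    fdr_threshold: float
    sig_mask: np.ndarray  # bool per vertex
    design_columns: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


def _global_design(
    subjects: list[SubjectRecord], nuisance: tuple[str, ...]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix of intercept, group and nuisance columns.

    Subjects missing a required covariate are dropped globally (mask
    returned).  Patient-only covariates use patient-deviation coding.
    """
    groups = np.array([1.0 if s.group == "patient" else 0.0 for s in subjects])
    cols = [np.ones(len(subjects)), groups]
    names = ["intercept", "group"]
    raw = {
        name: np.array([float(s.covariates.get(name, np.nan)) for s in subjects])
        for name in nuisance
    }
    keep = np.ones(len(subjects), dtype=bool)
    for name in nuisance:
        v = raw[name]
        if name in PATIENT_ONLY:
            keep &= ~(np.isnan(v) & (groups == 1))
        else:
            keep &= ~np.isnan(v)
    for name in nuisance:
        v = raw[name].copy()
        if name in PATIENT_ONLY:
            pat = (groups == 1) & keep
            if pat.any():
                v[pat] = v[pat] - np.nanmean(v[pat])
            v[groups == 0] = 0.0
        else:
            v = v - np.nanmean(v[keep])
        cols.append(v)
        names.append(name)
    x = np.column_stack(cols)
    xk = x[keep]
    if np.linalg.matrix_rank(xk) < xk.shape[1]:
        raise DesignError(
            "global design is rank deficient; drop a redundant nuisance covariate "
            "(constant or collinear column, e.g. a patient-only covariate with no "
            "variance across patients)"
        )
    return x, names, keep


def fit_vertex_glm(subjects: list[SubjectRecord], design: DesignSpec) -> GlmResult:
    """Fit the per-vertex OLS group model and FDR-threshold its p map.

    Listwise deletion per vertex for missing map values; global deletion for
    missing covariates.  Vertices whose local design is rank deficient or
    leaves no residual degrees of freedom are missing (and excluded from the
    FDR family).  Fully deterministic.
    """
    if len(subjects) < 4:
        raise DesignError("need at least 2 subjects per group")
    n_groups = {s.group for s in subjects}
    if n_groups != {"patient", "control"}:
        raise DesignError(f"need both groups present, got {sorted(n_groups)}")
    n_vertices = len(next(iter(subjects[0].maps.values())))
    y = np.stack([s.maps[design.outcome].values for s in subjects])  # (n, V)
    if y.shape[1] != n_vertices:
        raise DesignError("outcome maps disagree on vertex count")
    x_glob, names, keep = _global_design(subjects, design.nuisance)
    regs = [
        np.stack([s.maps[name].values for s in subjects]) for name in design.pervertex_regressors
    ]
    names = names + list(design.pervertex_regressors)
    p_cols = x_glob.shape[1] + len(regs)

    y = y[keep]
    x_glob = x_glob[keep]
    regs = [r[keep] for r in regs]
    n_subj = keep.sum()

    valid_rows = ~np.isnan(y)
    for r in regs:
        valid_rows &= ~np.isnan(r)

    beta = np.full(n_vertices, np.nan)
    tval = np.full(n_vertices, np.nan)
    pval = np.full(n_vertices, np.nan)
    df_out = np.zeros(n_vertices, dtype=np.int64)
    n_used = np.zeros(n_vertices, dtype=np.int64)
    g_col = names.index("group")

    complete = valid_rows.all(axis=0)
    if complete.any():
        _fit_batch(
            y[:, complete],
            x_glob,
            [r[:, complete] for r in regs],
            g_col,
            complete,
            beta,
            tval,
            pval,
            df_out,
            n_used,
        )
    for v in np.flatnonzero(~complete):
        rows = valid_rows[:, v]
        df = int(rows.sum()) - p_cols
        if df <= 0:
            continue
        _fit_batch(
            y[rows, v : v + 1],
            x_glob[rows],
            [r[rows, v : v + 1] for r in regs],
            g_col,
            np.array([v]),
            beta,
            tval,
            pval,
            df_out,
            n_used,
        )

    p_map = VertexMap(pval, name=f"p[{design.outcome}~group]")
    thr, sig = fdr_threshold(p_map, design.fdr_q)
    return GlmResult(
        beta_group=VertexMap(beta, name=f"beta_group[{design.outcome}]"),
        t_stat=VertexMap(tval, name=f"t[{design.outcome}~group]"),
        p_value=p_map,
        df=df_out,
        n_used=n_used,
        fdr_threshold=thr,
        sig_mask=sig,
        design_columns=names,
    )


def _fit_batch(
    y: np.ndarray,
    x_glob: np.ndarray,
    regs: list[np.ndarray],
    g_col: int,
    vertices: np.ndarray,
    beta: np.ndarray,
    tval: np.ndarray,
    pval: np.ndarray,
    df_out: np.ndarray,
    n_used: np.ndarray,
) -> None:
    """OLS at a batch of vertices sharing one subject subset.

    ``vertices`` may be a boolean mask or an index array into the output
    maps; ``y``/``regs`` are (n_subj, n_batch).  Per-vertex regressors are
    demeaned across subjects per vertex, and the normal equations are solved
    batched; ill-conditioned vertices stay missing.
    """
    n, nb = y.shape
    p = x_glob.shape[1] + len(regs)
    df = n - p
    if df <= 0:
        return
    x = np.broadcast_to(x_glob[None], (nb, n, x_glob.shape[1]))
    if regs:
        demeaned = [r - r.mean(axis=0, keepdims=True) for r in regs]
        x = np.concatenate([x] + [d.T[:, :, None] for d in demeaned], axis=2)
    else:
        x = np.ascontiguousarray(x)
    yt = y.T[:, :, None]  # (nb, n, 1)
    xtx = np.swapaxes(x, 1, 2) @ x
    xty = np.swapaxes(x, 1, 2) @ yt
    ok = np.linalg.cond(xtx) < 1e10
    b = np.full((nb, p, 1), np.nan)
    xtx_inv = np.full_like(xtx, np.nan)
    if ok.any():
        xtx_inv[ok] = np.linalg.inv(xtx[ok])
        b[ok] = xtx_inv[ok] @ xty[ok]
    resid = yt - x @ b
    ssr = (resid[:, :, 0] ** 2).sum(axis=1)
    ssy = (y**2).sum(axis=0)
    # a perfect fit leaves only rounding noise in the residuals; the group
    # t would then be a ratio of two ~eps quantities — define it as 0
    perfect = ssr <= 1e-20 * np.maximum(ssy, 1e-300)
    sigma2 = ssr / df
    se = np.sqrt(sigma2 * xtx_inv[:, g_col, g_col])
    bg = b[:, g_col, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(perfect | (se == 0), 0.0, bg / se)
    bg = np.where(perfect, 0.0, bg)
    pv = 2.0 * t_dist.sf(np.abs(t), df)
    bad = ~ok | ~np.isfinite(t)
    bg[bad] = np.nan
    t[bad] = np.nan
    pv[bad] = np.nan
    beta[vertices] = bg
    tval[vertices] = t
    pval[vertices] = pv
    df_out[vertices] = np.where(bad, 0, df)
    n_used[vertices] = np.where(bad, 0, n)


def fdr_threshold(p_values: VertexMap, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Step-up Benjamini-Hochberg over the non-missing vertices.

    Returns (threshold, sig_mask): threshold is the largest ordered p with
    p_(i) <= i*q/m over the m non-missing p values (0.0 when none
    qualifies, giving an empty mask).  One family pooled across everything
    passed in — callers who want per-hemisphere control call this per
    hemisphere.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    p = p_values.values
    valid = ~p_values.missing
    m = int(valid.sum())
    if m == 0:
        return 0.0, np.zeros(len(p), dtype=bool)
    ps = np.sort(p[valid])
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ps <= crit)
    if passing.size == 0:
        return 0.0, np.zeros(len(p), dtype=bool)
    thr = float(ps[passing[-1]])
    return thr, valid & (p <= thr)


@dataclass
class ClusterReport:
    """Connected-component summary of a significance mask."""

    n_significant: int
    n_components: int
    largest_component: int
    component_labels: np.ndarray  # -1 outside mask
    n_in_patch: int | None = None
    n_out_patch: int | None = None
    dice: float | None = None


def summarize_clusters(
    sig_mask: np.ndarray,
    mesh: TriangleMesh,
    reference_patch: np.ndarray | None = None,
) -> ClusterReport:
    """Label connected components of a vertex mask and, when a reference
    patch is given, report overlap counts and the Dice coefficient."""
    sig_mask = np.asarray(sig_mask, dtype=bool)
    labels = np.full(mesh.n_vertices, -1, dtype=np.int64)
    n_comp = 0
    largest = 0
    if sig_mask.any():
        # restrict by slicing (not multiplication): explicit zeros would be
        # treated as edges by csgraph
        sub = adjacency_matrix(mesh)[sig_mask][:, sig_mask]
        n_comp, lab = connected_components(sub, directed=False)
        _, counts = np.unique(lab, return_counts=True)
        labels[sig_mask] = lab
        largest = int(counts.max())
    report = ClusterReport(
        n_significant=int(sig_mask.sum()),
        n_components=n_comp,
        largest_component=largest,
        component_labels=labels,
    )
    if reference_patch is not None:
        patch = np.asarray(reference_patch, dtype=bool)
        inter = int((sig_mask & patch).sum())
        report.n_in_patch = inter
        report.n_out_patch = int((sig_mask & ~patch).sum())
        denom = int(sig_mask.sum()) + int(patch.sum())
        report.dice = 2.0 * inter / denom if denom else 0.0
    return report
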