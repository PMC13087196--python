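"""Multimorbidity-state clustering over quantile-defined timepoints.

Multimorbid patients' accrued diagnosis combinations are snapshotted at the
start of follow-up and at the cohort-level 25/50/75/90% quantiles of
diagnosis timing.  The pooled patient × block incidence matrices (both sexes,
all timepoints) are embedded with multiple correspondence analysis — the
correspondence analysis of the complete disjunctive 0/1 table — and the
retained coordinates are clustered with k-means, with the Calinski–Harabasz
index and within-cluster dispersion guiding the choice of k.  Movements
between clusters across timepoints, including the absorbing states *died*
and *no follow-up*, are tabulated in a Sankey-ready transition table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .records import Cohort

__all__ = [
    "Snapshot",
    "build_snapshots",
    "stack_snapshots",
    "MCAResult",
    "mca_embed",
    "ClusterModel",
    "kmeans_select",
    "tabulate_transitions",
    "cluster_enrichment",
]

logger = logging.getLogger(__name__)

PRESENT, DIED, NO_FOLLOWUP = "present", "died", "no_followup"


@dataclass
class Snapshot:
    """Diagnosis incidence of surviving multimorbid patients at one timepoint."""

    label: str
    t_days: float
    matrix: pd.DataFrame  # index patient_id, columns block_id, values {0,1}
    status: pd.Series  # per patient: present / died / no_followup


def build_snapshots(
    cohort: Cohort, quantile_days, include_t0: bool = True
) -> list[Snapshot]:
    """Snapshot accrued diagnosis combinations at each timepoint.

    Timepoints are days since each patient's first diagnosis; with
    ``include_t0`` a snapshot immediately after first presentation (t = 0) is
    prepended.  A patient whose death or end of follow-up falls at or before
    a timepoint is absorbed (``died`` / ``no_followup``) and contributes no
    incidence row there or later.  Only multimorbid patients (>= 2 blocks)
    are included.
    """
    cohort = cohort.multimorbid()
    ev = cohort.events
    if ev.empty:
        raise ValueError("no multimorbid patients to snapshot")
    timepoints = ([0.0] if include_t0 else []) + [float(t) for t in quantile_days]
    if not timepoints:
        raise ValueError("no timepoints requested")

    first = ev.groupby("patient_id")["diagnosis_date"].min()
    meta = cohort.meta.set_index("patient_id").loc[first.index]
    death_days = (pd.to_datetime(meta["death_date"]) - first).dt.days.astype(float)
    followup_days = (pd.to_datetime(meta["followup_end"]) - first).dt.days.astype(float)
    followup_days = followup_days.fillna(np.inf)

    blocks = sorted(ev["block_id"].unique())
    incidence = ev.pivot_table(
        index="patient_id", columns="block_id", values="days_since_first", aggfunc="min"
    ).reindex(columns=blocks)

    snapshots = []
    for i, t in enumerate(timepoints):
        died = death_days.notna() & (death_days <= t) & (t > 0)
        lost = ~died & (followup_days <= t) & (t > 0)
        status = pd.Series(PRESENT, index=incidence.index, name="status")
        status[died] = DIED
        status[lost] = NO_FOLLOWUP
        present = status.index[status == PRESENT]
        mat = (incidence.loc[present] <= t).astype(np.int8)
        if mat.empty:
            raise ValueError(f"no patients remain at timepoint t={t}")
        snapshots.append(Snapshot(label=f"t{i}", t_days=t, matrix=mat, status=status))
    return snapshots


def stack_snapshots(snapshots: list[Snapshot]) -> pd.DataFrame:
    """Pool snapshot rows into one matrix indexed by (timepoint, patient)."""
    return pd.concat(
        {s.label: s.matrix for s in snapshots}, names=["timepoint", "patient_id"]
    )


@dataclass
class MCAResult:
    """Row coordinates and inertia decomposition of an MCA embedding."""

    coordinates: pd.DataFrame  # rows aligned with the input, columns dim1..dimK
    eigenvalues: np.ndarray  # principal inertias of all non-trivial axes
    explained_inertia: np.ndarray  # eigenvalues / total inertia
    dropped_columns: list[str]


def mca_embed(matrix: pd.DataFrame, n_components: int | None = None) -> MCAResult:
    """Multiple correspondence analysis of a binary incidence matrix.

    Each block is treated as a two-category variable (absent/present), giving
    the complete disjunctive table Z = [X, 1-X]; row principal coordinates
    come from the generalised SVD of the centred, mass-weighted
    correspondence matrix.  Constant columns carry a single category and are
    dropped with a log entry.  ``n_components`` above the available rank is
    clamped with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    keep = (X.var(axis=0) > 0)
    dropped = [c for c, k in zip(matrix.columns, keep) if not k]
    if dropped:
        logger.info("MCA dropping %d constant columns: %s", len(dropped), dropped[:5])
        X = X[:, keep]
    n, q = X.shape
    if q == 0:
        raise ValueError("no non-constant columns left for MCA")
    Z = np.hstack([X, 1.0 - X])  # complete disjunctive table, 2q categories
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    nontrivial = sv > 1e-12
    sv = sv[nontrivial]
    U = U[:, nontrivial]
    rank = sv.size
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; clamped")
        n_components = rank
    coords = (U * sv) / np.sqrt(r)[:, None]
    eigenvalues = sv**2
    coords_df = pd.DataFrame(
        coords[:, :n_components],
        index=matrix.index,
        columns=[f"dim{k + 1}" for k in range(n_components)],
    )
    return MCAResult(
        coordinates=coords_df,
        eigenvalues=eigenvalues,
        explained_inertia=eigenvalues / eigenvalues.sum(),
        dropped_columns=dropped,
    )


@dataclass
class ClusterModel:
    """k-means model over MCA coordinates with selection diagnostics."""

    k: int
    assignments: pd.Series  # cluster labels 1..k, aligned with coordinate rows
    centroids: np.ndarray
    diagnostics: pd.DataFrame  # per candidate k: inertia (WSS) and CH score
    seed: int


def kmeans_select(
    coordinates: pd.DataFrame,
    k_grid=range(2, 11),
    n_init: int = 25,
    seed: int = 0,
    k_final: int = 6,
) -> ClusterModel:
    """Run best-of-``n_init`` k-means over a grid of k and fit the final model.

    Within-cluster sum of squares (elbow) and the Calinski–Harabasz score are
    reported for every candidate k; the returned assignments use ``k_final``
    (the selection itself is a judgement call made from the diagnostics).
    """
    X = coordinates.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("coordinates must be finite")
    ks = sorted(set(list(k_grid) + [k_final]))
    if max(ks) > len(X):
        raise ValueError(f"k={max(ks)} exceeds number of points {len(X)}")
    diag_rows = []
    final = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        ch = calinski_harabasz_score(X, km.labels_) if k >= 2 else np.nan
        diag_rows.append({"k": k, "inertia": km.inertia_, "calinski_harabasz": ch})
        if k == k_final:
            final = km
    assignments = pd.Series(
        final.labels_ + 1, index=coordinates.index, name="cluster"
    )
    return ClusterModel(
        k=k_final,
        assignments=assignments,
        centroids=final.cluster_centers_,
        diagnostics=pd.DataFrame(diag_rows),
        seed=seed,
    )


def tabulate_transitions(
    assignments: pd.Series, snapshots: list[Snapshot]
) -> pd.DataFrame:
    """Count flows between cluster states across consecutive timepoints.

    ``assignments`` must be indexed by (timepoint, patient_id) as produced by
    clustering :func:`stack_snapshots` rows.  Absorbing states (*died*,
    *no_followup*) receive inflows when a patient drops out and self-flows
    afterwards, so state occupancy is conserved at every timepoint.  Output
    columns ``source, target, value`` use ``"<timepoint>:<state>"`` labels,
    ready for Sankey renderers.
    """
    labels = [s.label for s in snapshots]
    status = pd.DataFrame({s.label: s.status for s in snapshots})
    state = pd.DataFrame(index=status.index, columns=labels, dtype=object)
    for s in snapshots:
        present = s.status == PRESENT
        cl = assignments.loc[s.label]
        missing = s.status.index[present].difference(cl.index)
        if len(missing):
            raise ValueError(
                f"no cluster assignment at {s.label} for {len(missing)} present patients"
            )
        state.loc[present, s.label] = "c" + cl.loc[s.status.index[present]].astype(str)
        state.loc[~present, s.label] = status.loc[~present, s.label]
    flows = (
        pd.concat(
            [
                state.groupby([state[a], state[b]]).size().rename("value").reset_index()
                .assign(step=i)
                .rename(columns={a: "source_state", b: "target_state"})
                for i, (a, b) in enumerate(zip(labels, labels[1:]))
            ],
            ignore_index=True,
        )
        if len(labels) > 1
        else pd.DataFrame(columns=["source_state", "target_state", "value", "step"])
    )
    flows["source"] = [
        f"{labels[s]}:{st}" for s, st in zip(flows["step"], flows["source_state"])
    ]
    flows["target"] = [
        f"{labels[s + 1]}:{st}" for s, st in zip(flows["step"], flows["target_state"])
    ]
    return flows[["source", "target", "value"]]


def cluster_enrichment(
    assignments: pd.Series, stacked: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster block prevalence ratio against the pooled prevalence.

    The reporting statistic used to attach clinical labels (e.g.
    "cardiometabolic") to clusters; a ratio of 2 means carriers of the block
    are twice as frequent in the cluster as overall.
    """
    overall = stacked.mean()
    rows = []
    for cl, grp in stacked.groupby(assignments):
        ratio = grp.mean() / overall.replace(0, np.nan)
        for block, r in ratio.items():
            rows.append(
                {
                    "cluster": cl,
                    "block_id": block,
                    "cluster_prevalence": grp.mean()[block],
                    "overall_prevalence": overall[block],
                    "ratio": r,
                }
            )
    return pd.DataFrame(rows)
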