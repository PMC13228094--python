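"""Network-level graph metrics from an individual parcellation.

Per participant the pipeline produces, from the parcel-level Fisher-Z
connectivity matrix and the vertex assignment:

* within-network connectivity: mean Z over parcel pairs inside each network
  (missing when the network has fewer than 2 parcels),
* between-network connectivity: mean Z over parcel pairs spanning each
  unordered network pair,
* participation coefficient (PC): for binary graphs thresholded at tie
  densities 1%..25%, node PC_i = 1 - sum_s (k_is / k_i)^2; node PCs are
  averaged over the first 10 densities (1%-10%) and then over the parcels of
  each network,
* spatial extent: the number of vertices assigned to each network.

Edges are ranked by signed Z (no absolute value or sign filter) when
thresholding; ties are broken by ascending pair index.  Isolated nodes
contribute PC 0 at that density so the per-node average stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from emaconn.mapping import Parcellation, VertexAssignment, qc_retained_frames
from emaconn.timeseries import VertexTimeSeries

#: Correlations are clipped to +/- (1 - CLIP_EPS) before atanh.
CLIP_EPS = 1e-7


@dataclass
class ParcelConnectivity:
    """Parcels x parcels Fisher-Z matrix with per-parcel network labels."""

    z: np.ndarray
    labels: np.ndarray
    network_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.z.shape != (self.labels.size, self.labels.size):
            raise ValueError("z must be square with one row per parcel")
        if not np.isfinite(self.z).all():
            raise ValueError("z entries must be finite")

    @property
    def n_parcels(self) -> int:
        return self.labels.size


def parcel_timeseries(
    ts: VertexTimeSeries, parcellation: Parcellation
) -> np.ndarray:
    """Mean member-vertex signal per parcel, retained frames only."""
    if parcellation.n_parcels == 0:
        raise ValueError("parcellation has no parcels")
    data = ts.retained()
    return np.stack(
        [data[verts].mean(axis=0) for verts in parcellation.parcel_vertices]
    )


def fisher_z(r):
    """Fisher Z (atanh) transform, clipping |r| to 1 - 1e-7 first.

    Accepts scalars or arrays; raises for |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) > 1).any():
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(arr, -1 + CLIP_EPS, 1 - CLIP_EPS))
    return float(z) if np.isscalar(r) else z


def parcel_connectivity(
    parcel_ts: np.ndarray,
    parcellation: Parcellation,
) -> ParcelConnectivity:
    """Fisher-Z parcel connectivity from parcel-mean time series."""
    r = np.corrcoef(parcel_ts)
    r = np.atleast_2d(r)
    z = fisher_z(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(z, 0.0)
    return ParcelConnectivity(
        z=z,
        labels=np.asarray(parcellation.parcel_labels, dtype=np.int64),
        network_ids=tuple(parcellation.network_ids),
    )


def within_between(
    pc_mat: ParcelConnectivity,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Mean Z within each network and between each unordered network pair.

    Within-network values are NaN for networks with fewer than 2 parcels;
    between-network values are NaN when either network has no parcel.  The
    diagonal never enters any average.
    """
    ids = pc_mat.network_ids
    labels = pc_mat.labels
    z = pc_mat.z
    within: dict[str, float] = {}
    between: dict[tuple[str, str], float] = {}
    for a, name_a in enumerate(ids):
        idx_a = np.flatnonzero(labels == a)
        if idx_a.size >= 2:
            block = z[np.ix_(idx_a, idx_a)]
            iu = np.triu_indices(idx_a.size, k=1)
            within[name_a] = float(block[iu].mean())
        else:
            within[name_a] = float("nan")
        for b in range(a + 1, len(ids)):
            idx_b = np.flatnonzero(labels == b)
            key = (name_a, ids[b])
            if idx_a.size and idx_b.size:
                between[key] = float(z[np.ix_(idx_a, idx_b)].mean())
            else:
                between[key] = float("nan")
    return within, between


def _binary_graph_at_density(
    z: np.ndarray, density: float
) -> tuple[np.ndarray, np.ndarray]:
    """Top ``floor(density * P)`` off-diagonal edges by signed Z.

    Returns (rows, cols) of kept undirected edges.  Ties broken by ascending
    pair index (row-major upper triangle).
    """
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    m = int(np.floor(density * w.size))
    if m == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    order = np.argsort(-w, kind="stable")[:m]
    return iu[order], ju[order]


def participation_coefficients(
    pc_mat: ParcelConnectivity,
    densities: np.ndarray | None = None,
    avg_over: int = 10,
) -> dict[str, float]:
    """Per-network mean participation coefficient over a tie-density grid.

    Binary graphs are built at every density of ``densities`` (default 1%
    to 25% in 1% steps); each parcel's PC is averaged over the first
    ``avg_over`` densities of the grid (default the 1%-10% graphs), then
    parcel PCs are averaged within each network.  Networks with no parcels
    get NaN.
    """
    if pc_mat.n_parcels < 2:
        raise ValueError("participation coefficients require at least 2 parcels")
    if densities is None:
        densities = np.arange(1, 26) / 100.0
    densities = np.asarray(densities, dtype=float)
    if avg_over < 1 or avg_over > densities.size:
        raise ValueError("avg_over must be within the density grid")
    n = pc_mat.n_parcels
    labels = pc_mat.labels
    K = len(pc_mat.network_ids)
    node_pc = np.zeros((avg_over, n))
    for d_i, d in enumerate(densities[:avg_over]):
        rows, cols = _binary_graph_at_density(pc_mat.z, d)
        k_is = np.zeros((n, K))
        np.add.at(k_is, (rows, labels[cols]), 1.0)
        np.add.at(k_is, (cols, labels[rows]), 1.0)
        k_i = k_is.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = k_is / k_i[:, None]
            pc = 1.0 - np.nansum(frac**2, axis=1)
        pc[k_i == 0] = 0.0  # isolated nodes
        node_pc[d_i] = pc
    mean_node_pc = node_pc.mean(axis=0)
    out: dict[str, float] = {}
    for k, name in enumerate(pc_mat.network_ids):
        idx = np.flatnonzero(labels == k)
        out[name] = float(mean_node_pc[idx].mean()) if idx.size else float("nan")
    return out


def spatial_extent(assignment: VertexAssignment) -> dict[str, int]:
    """Vertex count per network; UNASSIGNED excluded, absent networks 0."""
    out = {}
    for k, name in enumerate(assignment.network_ids):
        out[name] = int((assignment.labels == k).sum())
    return out


def participant_metrics(
    ts: VertexTimeSeries,
    assignment: VertexAssignment,
    parcellation: Parcellation,
) -> dict[str, float]:
    """One participant's metric row: within/between Z, PC, spatial extent."""
    pts = parcel_timeseries(ts, parcellation)
    pc_mat = parcel_connectivity(pts, parcellation)
    within, between = within_between(pc_mat)
    pcs = participation_coefficients(pc_mat)
    extent = spatial_extent(assignment)
    row: dict[str, float] = {}
    for name, v in within.items():
        row[f"within_{name}"] = v
    for (a, b), v in between.items():
        row[f"between_{a}_{b}"] = v
    for name, v in pcs.items():
        row[f"pc_{name}"] = v
    for name, v in extent.items():
        row[f"extent_{name}"] = float(v)
    return row


def metrics_table(
    participants: dict[str, tuple[VertexTimeSeries, VertexAssignment, Parcellation]],
    mean_fd: dict[str, float] | None = None,
    min_frames: int = 375,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant metric table with frame-count QC.

    ``participants`` maps participant id to (time series, assignment,
    parcellation).  Participants failing the retained-frame rule are listed
    in the QC report and omitted from the table.
    """
    rows = []
    qc: dict[str, list | int] = {"excluded": [], "included": 0,
                                 "min_frames": min_frames}
    for pid, (ts, assignment, parcellation) in participants.items():
        if not qc_retained_frames(ts.censor_mask, minimum=min_frames):
            qc["excluded"].append(
                {"participant_id": pid, "retained_frames": ts.n_retained}
            )
            continue
        row = {"participant_id": pid}
        row.update(participant_metrics(ts, assignment, parcellation))
        if mean_fd is not None:
            row["mean_fd"] = mean_fd[pid]
        rows.append(row)
    qc["included"] = len(rows)
    return pd.DataFrame(rows), qc
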