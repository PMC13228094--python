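"""Individual-specific network mapping by template matching.

The algorithm, applied per participant:

1. clean the vertex time series (censor, demean/detrend, nuisance
   regression, band-pass 0.01-0.1 Hz),
2. compute the dense vertex-to-vertex Pearson correlation matrix over
   retained frames,
3. binarize each vertex's connectivity row at the top 5% of connections,
4. score the binarized map against every a-priori network template with the
   Dice coefficient and assign the vertex to the best-matching network,
5. remove contiguous same-network patches smaller than 30 mm^2,
6. parcellate the assignment into connected components (one parcel per
   contiguous same-network patch).

Determinism notes: the top-fraction cut keeps exactly ``floor(fraction *
(n - 1))`` entries with ties at the cut broken by ascending vertex index, and
Dice ties are broken by the lowest network index; both tie kinds are counted
so they can be reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.sparse import csgraph

from emaconn.surface import SurfaceModel
from emaconn.templates import UNASSIGNED, NetworkTemplateSet
from emaconn.timeseries import VertexTimeSeries


@dataclass
class DenseConnectivity:
    """Symmetric vertex correlation matrix with a validity flag per vertex.

    Vertices with zero variance over retained frames are flagged invalid;
    their rows/columns are NaN and they are excluded downstream.
    """

    matrix: np.ndarray
    valid: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VertexAssignment:
    """Per-vertex network label (or UNASSIGNED) with the winning Dice value."""

    labels: np.ndarray
    dice: np.ndarray
    network_ids: tuple[str, ...]
    tie_count: int = 0

    def __post_init__(self) -> None:
        if self.labels.shape != self.dice.shape:
            raise ValueError("labels and dice must have equal length")
        k = len(self.network_ids)
        ok = (self.labels == UNASSIGNED) | ((self.labels >= 0) & (self.labels < k))
        if not ok.all():
            raise ValueError("labels must be network indices or UNASSIGNED")
        if ((self.dice < 0) | (self.dice > 1)).any():
            raise ValueError("dice values must lie in [0, 1]")


@dataclass
class Parcellation:
    """Connected same-network components ("parcels") of an assignment."""

    network_ids: tuple[str, ...]
    parcel_labels: list[int] = field(default_factory=list)
    parcel_vertices: list[np.ndarray] = field(default_factory=list)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_labels)


def clean_timeseries(
    ts: VertexTimeSeries,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.1),
) -> VertexTimeSeries:
    """Demean, detrend, nuisance-regress, and band-pass a time series.

    Regression coefficients (intercept, linear trend, nuisance columns) are
    fit on retained frames only and the fitted waveforms subtracted from all
    frames.  Before filtering, censored-frame values are replaced by linear
    interpolation over retained frames so motion-contaminated samples cannot
    bleed into their neighbors through the band-pass (2nd-order Butterworth,
    forward-backward, applied over the full frame axis so the filter sees a
    contiguous series).  The censor mask is carried through unchanged.
    Nuisance columns collinear with the intercept (constant columns) are
    dropped with a warning.
    """
    T = ts.n_frames
    low, high = band
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0 <= low < high < nyquist:
        raise ValueError(
            f"band must satisfy 0 <= low < high < Nyquist ({nyquist:.3f} Hz)"
        )
    cols = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] == T and nuisance.shape[1] != T:
            nuisance = nuisance.T
        if nuisance.shape[1] != T:
            raise ValueError("nuisance rows must align with frames")
        for j, reg in enumerate(nuisance):
            if np.ptp(reg) == 0:
                warnings.warn(
                    f"nuisance regressor {j} is constant; dropped", stacklevel=2
                )
                continue
            cols.append(reg)
    X = np.stack(cols, axis=1)  # T x p
    keep = ts.censor_mask
    if keep.sum() < X.shape[1]:
        raise ValueError("fewer retained frames than regression columns")
    beta, *_ = np.linalg.lstsq(X[keep], ts.data[:, keep].T, rcond=None)
    resid = ts.data - (X @ beta).T
    if not keep.all():
        frames = np.arange(T)
        for v in range(resid.shape[0]):
            resid[v, ~keep] = np.interp(frames[~keep], frames[keep], resid[v, keep])
    if low > 0:
        b, a = sps.butter(2, [low / nyquist, high / nyquist], btype="band")
    else:
        b, a = sps.butter(2, high / nyquist, btype="low")
    filtered = sps.filtfilt(b, a, resid, axis=1)
    return VertexTimeSeries(data=filtered, censor_mask=keep.copy(), tr=ts.tr)


def qc_retained_frames(mask: np.ndarray, minimum: int = 375) -> bool:
    """Inclusion rule: at least ``minimum`` retained frames."""
    return int(np.asarray(mask, dtype=bool).sum()) >= minimum


def vertex_connectivity(ts: VertexTimeSeries) -> DenseConnectivity:
    """Pairwise Pearson correlation over retained frames.

    Requires at least two retained frames.  Zero-variance vertices are
    flagged invalid (NaN row/column) rather than raising, since downstream
    assignment simply leaves them unassigned.
    """
    if ts.n_retained < 2:
        raise ValueError("need at least 2 retained frames for correlation")
    data = ts.retained()
    # ptp catches constant series exactly; std of a constant row is only
    # zero up to rounding
    valid = (np.ptp(data, axis=1) > 0) & (data.std(axis=1) > 0)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} zero-variance vertices flagged invalid",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data)
    mat[~valid, :] = np.nan
    mat[:, ~valid] = np.nan
    np.clip(mat, -1.0, 1.0, out=mat)
    return DenseConnectivity(matrix=mat, valid=valid)


def binarize_top_fraction(values: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Binary map of the ``floor(fraction * len(values))`` strongest entries.

    ``values`` is one vertex's connectivity to every *other* vertex (the
    self-connection is excluded before calling).  Ties at the cut are broken
    by ascending index, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    m = int(np.floor(fraction * values.size))
    if m < 1:
        raise ValueError(
            f"fraction {fraction} of {values.size} entries keeps no connection"
        )
    # stable sort of descending value; equal values keep ascending index
    order = np.argsort(-values, kind="stable")
    if m < values.size and values[order[m - 1]] == values[order[m]]:
        warnings.warn("ties at the top-fraction cut; broken by index", stacklevel=2)
    out = np.zeros(values.size, dtype=bool)
    out[order[:m]] = True
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two binary maps.

    Defined as 0 when both maps are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def assign_vertices(
    conn: DenseConnectivity,
    templates: NetworkTemplateSet,
    fraction: float = 0.05,
) -> VertexAssignment:
    """Assign every vertex to the template network with the highest Dice.

    Each vertex's connectivity row (self-connection excluded) is binarized at
    the top ``fraction``; its Dice coefficient against every template map is
    computed and the argmax network assigned.  Vertices whose Dice is zero
    against every template, and invalid (zero-variance) vertices, are left
    UNASSIGNED.  Exact Dice ties go to the lowest network index and are
    counted in ``tie_count``.
    """
    n = conn.n_vertices
    if templates.n_vertices != n:
        raise ValueError("templates and connectivity are on different surfaces")
    m = int(np.floor(fraction * (n - 1)))
    if m < 1:
        raise ValueError("fraction keeps no connection on this surface")
    mat = conn.matrix.copy()
    np.fill_diagonal(mat, -np.inf)
    mat[~conn.valid, :] = -np.inf
    # stable argsort on negated values: ties at the cut resolve by ascending
    # column index, matching binarize_top_fraction
    order = np.argsort(-mat, axis=1, kind="stable")[:, :m]
    binmaps = np.zeros((n, n), dtype=bool)
    np.put_along_axis(binmaps, order, True, axis=1)
    tmpl = templates.maps
    inter = binmaps @ tmpl.T.astype(np.float64)  # n x K
    sizes = tmpl.sum(axis=1).astype(np.float64)
    dice_mat = 2.0 * inter / (m + sizes[None, :])
    best = np.argmax(dice_mat, axis=1)
    best_dice = dice_mat[np.arange(n), best]
    ties = int(
        ((dice_mat == best_dice[:, None]).sum(axis=1) > 1)[best_dice > 0].sum()
    )
    labels = best.astype(np.int64)
    labels[best_dice <= 0] = UNASSIGNED
    labels[~conn.valid] = UNASSIGNED
    out_dice = np.where(labels == UNASSIGNED, 0.0, best_dice)
    return VertexAssignment(
        labels=labels,
        dice=out_dice,
        network_ids=tuple(templates.network_ids),
        tie_count=ties,
    )


def _label_components(
    labels: np.ndarray, surface: SurfaceModel
) -> list[tuple[int, np.ndarray]]:
    """Connected components of same-labeled vertices (UNASSIGNED skipped)."""
    comps: list[tuple[int, np.ndarray]] = []
    for lab in np.unique(labels):
        if lab == UNASSIGNED:
            continue
        idx = np.flatnonzero(labels == lab)
        sub = surface.adjacency[idx][:, idx]
        n_comp, memb = csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            comps.append((int(lab), idx[memb == c]))
    return comps


def remove_small_patches(
    assignment: VertexAssignment,
    surface: SurfaceModel,
    min_area: float = 30.0,
) -> VertexAssignment:
    """Unassign contiguous patches with surface area strictly below ``min_area``.

    Area of a patch is its vertex count times ``surface.vertex_area`` (mm^2);
    patches with area >= ``min_area`` are untouched (the rule is a strict
    inequality).  Removed vertices become UNASSIGNED, not reassigned.
    """
    labels = assignment.labels.copy()
    dice_vals = assignment.dice.copy()
    removed = 0
    for _, verts in _label_components(assignment.labels, surface):
        if verts.size * surface.vertex_area < min_area:
            labels[verts] = UNASSIGNED
            dice_vals[verts] = 0.0
            removed += 1
    out = VertexAssignment(
        labels=labels,
        dice=dice_vals,
        network_ids=assignment.network_ids,
        tie_count=assignment.tie_count,
    )
    out.removed_patches = removed  # type: ignore[attr-defined]
    return out


def parcellate(assignment: VertexAssignment, surface: SurfaceModel) -> Parcellation:
    """One parcel per connected component of same-labeled vertices.

    UNASSIGNED vertices are excluded; the parcel count varies per
    participant.  Idempotent: parcellating a parcellation's implied labels
    reproduces the same parcels.
    """
    comps = _label_components(assignment.labels, surface)
    if not comps:
        warnings.warn("assignment has no labeled vertices; empty parcellation",
                      stacklevel=2)
    return Parcellation(
        network_ids=assignment.network_ids,
        parcel_labels=[lab for lab, _ in comps],
        parcel_vertices=[verts for _, verts in comps],
    )
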