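"""Synthetic BOLD-like signals with planted network structure.

Each vertex's signal is a weighted sum of three unit-variance latent sources:
a factor shared by the vertex's network, a global factor shared by all
vertices, and private noise,

    y_v(t) = sqrt(rho_w) * L_{s(v)}(t) + sqrt(rho_b) * G(t)
             + sqrt(1 - rho_w - rho_b) * eps_v(t),

so the expected Pearson correlation is ``rho_w + rho_b`` within a network and
``rho_b`` between networks.  This factor model deliberately omits hemodynamic
convolution: the template-matching algorithm depends only on the correlation
structure of the signals.  An optional AR(1) coefficient adds temporal
autocorrelation to every latent source (standardized back to unit variance),
which leaves the spatial correlation structure unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from emaconn.surface import SurfaceModel
from emaconn.templates import UNASSIGNED
from emaconn.timeseries import VertexTimeSeries


@dataclass(frozen=True)
class BOLDSimConfig:
    """Configuration of the resting-state signal generator.

    Defaults mirror an HCP-style acquisition: two runs of 460 frames at
    TR = 0.8 s.  ``fd_mean``/``fd_sd`` parameterize the lognormal from which
    each participant's mean framewise displacement (mm) is drawn; FD is used
    downstream only as a covariate and is not mechanistically coupled to the
    censoring process, which is independent Bernoulli per frame.
    """

    frames_per_run: int = 460
    n_runs: int = 2
    within_corr: float = 0.5
    between_corr: float = 0.0
    censor_prob: float = 0.0
    fd_mean: float = 0.15
    fd_sd: float = 0.08
    ar1: float = 0.0
    tr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames_per_run < 1 or self.n_runs < 1:
            raise ValueError("frames_per_run and n_runs must be positive")
        if not 0 <= self.within_corr < 1:
            raise ValueError("within_corr must be in [0, 1)")
        if not 0 <= self.between_corr <= self.within_corr:
            raise ValueError("between_corr must be in [0, within_corr]")
        if self.within_corr + self.between_corr >= 1:
            raise ValueError("within_corr + between_corr must be < 1")
        if not 0 <= self.censor_prob < 1:
            raise ValueError("censor_prob must be in [0, 1)")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return self.frames_per_run * self.n_runs


def _latents(rng: np.random.Generator, shape: tuple[int, ...], ar1: float) -> np.ndarray:
    """Standard-normal latents, optionally AR(1)-filtered to unit variance."""
    x = rng.standard_normal(shape)
    if ar1 > 0:
        x = sps.lfilter([1.0], [1.0, -ar1], x, axis=-1)
        x *= np.sqrt(1.0 - ar1**2)
    return x


def simulate_bold(
    surface: SurfaceModel,
    assignment: np.ndarray,
    cfg: BOLDSimConfig,
) -> tuple[VertexTimeSeries, float]:
    """Simulate one participant's vertex time series.

    ``assignment`` must label every vertex of ``surface`` with a network id
    (no UNASSIGNED entries).  Returns the time series (censor mask included)
    and the participant's mean framewise displacement in mm.  Output is
    bit-identical for identical configuration and seed.
    """
    assignment = np.asarray(assignment)
    if assignment.shape != (surface.n_vertices,):
        raise ValueError("assignment length must equal surface.n_vertices")
    if (assignment == UNASSIGNED).any():
        raise ValueError("assignment must cover the surface (no UNASSIGNED)")
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_frames
    labels, inv = np.unique(assignment, return_inverse=True)
    K = labels.size
    L = _latents(rng, (K, T), cfg.ar1)
    G = _latents(rng, (T,), cfg.ar1)
    eps = _latents(rng, (surface.n_vertices, T), cfg.ar1)
    rho_w, rho_b = cfg.within_corr, cfg.between_corr
    data = (
        np.sqrt(rho_w) * L[inv]
        + np.sqrt(rho_b) * G[None, :]
        + np.sqrt(1.0 - rho_w - rho_b) * eps
    )
    mask = rng.random(T) >= cfg.censor_prob
    # lognormal parameterized so the draw has mean fd_mean and SD fd_sd
    sigma2 = np.log1p((cfg.fd_sd / cfg.fd_mean) ** 2)
    mu = np.log(cfg.fd_mean) - sigma2 / 2.0
    mean_fd = float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))
    return VertexTimeSeries(data=data, censor_mask=mask, tr=cfg.tr), mean_fd
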