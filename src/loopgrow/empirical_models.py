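"""Empirical models guiding chain growth.

Two kinds of model are fitted from the loop database:

* per-separation bivariate Gaussian kernel density estimates over
  (d_prev, d_new) anchor-distance pairs, evaluated on a 32x32 grid,
  bilinearly interpolated, and sampled through their conditional slices
  f(d_new | d_prev);
* per-residue-type (phi, psi) frequency tables used to select a low-energy
  subset of trial placements.

The KDE uses a diagonal bandwidth built from the per-axis standard deviations
(Scott's rule for two dimensions, h_i = sigma_i * n^(-1/6), by default). The
upper tail of each axis is Winsorized before fitting to tame sparse extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import wrap_degrees

GRID_POINTS = 32
DEFAULT_WINSOR_LEVEL = 99.0
DEFAULT_PHI_PSI_BIN = 10.0
DEFAULT_PSEUDOCOUNT_FRACTION = 1e-6


class FitError(ValueError):
    """Raised when a model cannot be fitted from the supplied data."""


class SamplingError(RuntimeError):
    """Raised when a conditional slice carries no probability mass."""


@dataclass
class DistancePairSet:
    """Observed (d_prev, d_new) pairs at one residue separation ``g``."""

    g: int
    pairs: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        if self.g < 1:
            raise ValueError("separation g must be >= 1")
        if len(self.pairs) and not np.all(self.pairs > 0):
            raise ValueError("distances must be positive")


def winsorize(values, level: float = DEFAULT_WINSOR_LEVEL) -> np.ndarray:
    """Replace values above the ``level``-th percentile by that percentile.

    One-sided (upper tail only); order and count are preserved.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot winsorize empty input")
    if not (0 < level <= 100):
        raise ValueError("level must be in (0, 100]")
    cut = np.percentile(v, level)
    return np.minimum(v, cut)


@dataclass
class Kde2D:
    """2D Gaussian KDE evaluated on a 32x32 grid with bilinear interpolation.

    ``grid[i, j]`` is the density at ``(x_nodes[i], y_nodes[j])`` where x is
    d_prev and y is d_new.
    """

    x_nodes: np.ndarray
    y_nodes: np.ndarray
    grid: np.ndarray
    bandwidth: np.ndarray  # (2,) diagonal entries h_x, h_y
    n_data: int

    def __post_init__(self) -> None:
        if self.grid.shape != (len(self.x_nodes), len(self.y_nodes)):
            raise ValueError("grid shape mismatch")
        if np.any(self.grid < 0):
            raise ValueError("negative density on grid")
        if np.any(np.asarray(self.bandwidth) <= 0):
            raise ValueError("bandwidth must be positive definite")

    @property
    def domain(self) -> tuple[float, float, float, float]:
        return (
            float(self.x_nodes[0]),
            float(self.x_nodes[-1]),
            float(self.y_nodes[0]),
            float(self.y_nodes[-1]),
        )

    def grid_integral(self) -> float:
        """Trapezoidal integral of the grid density over the domain."""
        return float(np.trapezoid(np.trapezoid(self.grid, self.y_nodes, axis=1), self.x_nodes))


def kernel_sum(data: np.ndarray, bandwidth: np.ndarray, x, y) -> np.ndarray:
    """Brute-force diagonal-bandwidth Gaussian kernel sum at points (x, y).

    Reference implementation of the KDE definition; the fitted grid must agree
    with this to near machine precision.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    hx, hy = float(bandwidth[0]), float(bandwidth[1])
    dx = (x[:, None] - data[None, :, 0]) / hx
    dy = (y[:, None] - data[None, :, 1]) / hy
    k = np.exp(-0.5 * (dx * dx + dy * dy)) / (2.0 * np.pi * hx * hy)
    return k.mean(axis=1)


def fit_kde2d(
    data: DistancePairSet,
    winsor_level: float = DEFAULT_WINSOR_LEVEL,
    bandwidth_scale: float = 1.0,
) -> Kde2D:
    """Fit the gridded KDE to one separation's distance pairs.

    The grid domain is the Winsorized data range padded by two bandwidths per
    axis, so essentially all kernel mass falls inside it.
    """
    pairs = data.pairs
    if len(pairs) < 10:
        raise FitError(f"need >= 10 pairs to fit a KDE, got {len(pairs)}")
    w = np.column_stack([winsorize(pairs[:, 0], winsor_level), winsorize(pairs[:, 1], winsor_level)])
    n = len(w)
    sig = w.std(axis=0, ddof=1)
    if np.any(sig < 1e-9):
        raise FitError(
            "zero variance on an axis; add jitter to the distance pairs before fitting"
        )
    h = bandwidth_scale * sig * n ** (-1.0 / 6.0)
    lo = w.min(axis=0) - 2.0 * h
    hi = w.max(axis=0) + 2.0 * h
    x_nodes = np.linspace(lo[0], hi[0], GRID_POINTS)
    y_nodes = np.linspace(lo[1], hi[1], GRID_POINTS)
    xg, yg = np.meshgrid(x_nodes, y_nodes, indexing="ij")
    dens = kernel_sum(w, h, xg.ravel(), yg.ravel()).reshape(GRID_POINTS, GRID_POINTS)
    return Kde2D(x_nodes=x_nodes, y_nodes=y_nodes, grid=dens, bandwidth=h, n_data=n)


def _bracket(nodes: np.ndarray, q: float) -> tuple[int, float]:
    """Cell index and fractional offset for a query inside [nodes0, nodes-1]."""
    i = int(np.searchsorted(nodes, q) - 1)
    i = min(max(i, 0), len(nodes) - 2)
    t = (q - nodes[i]) / (nodes[i + 1] - nodes[i])
    return i, float(t)


def eval_density(kde: Kde2D, d_prev: float, d_new: float) -> float:
    """Bilinear interpolation of the grid; zero outside the domain."""
    x0, x1, y0, y1 = kde.domain
    if not (x0 <= d_prev <= x1 and y0 <= d_new <= y1):
        return 0.0
    i, tx = _bracket(kde.x_nodes, d_prev)
    j, ty = _bracket(kde.y_nodes, d_new)
    g = kde.grid
    return float(
        (1 - tx) * (1 - ty) * g[i, j]
        + tx * (1 - ty) * g[i + 1, j]
        + (1 - tx) * ty * g[i, j + 1]
        + tx * ty * g[i + 1, j + 1]
    )


def conditional_slice(kde: Kde2D, d_prev: float) -> np.ndarray:
    """Unnormalized density of d_new at the 32 y-nodes for fixed ``d_prev``.

    Bilinear along the d_prev axis; identically zero when d_prev is outside
    the domain.
    """
    x0, x1, *_ = kde.domain
    if not (x0 <= d_prev <= x1):
        return np.zeros_like(kde.y_nodes)
    i, tx = _bracket(kde.x_nodes, d_prev)
    return (1 - tx) * kde.grid[i, :] + tx * kde.grid[i + 1, :]


def slice_cdf(kde: Kde2D, d_prev: float) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and normalized trapezoidal CDF of the conditional slice."""
    f = conditional_slice(kde, d_prev)
    total = np.trapezoid(f, kde.y_nodes)
    if total <= 0:
        raise SamplingError(f"conditional slice at d_prev={d_prev:.3f} has no mass")
    y = kde.y_nodes
    seg = 0.5 * (f[1:] + f[:-1]) * np.diff(y)
    cdf = np.concatenate([[0.0], np.cumsum(seg)]) / total
    cdf[-1] = 1.0
    return y, cdf


def sample_conditional(
    kde: Kde2D, d_prev: float, rng: np.random.Generator, size: int | None = None
) -> float | np.ndarray:
    """Inverse-CDF draw(s) from f(d_new | d_prev) with linear interpolation
    within grid cells. Raises :class:`SamplingError` on an all-zero slice."""
    y, cdf = slice_cdf(kde, d_prev)
    u = rng.random(size if size is not None else 1)
    idx = np.clip(np.searchsorted(cdf, u, side="right") - 1, 0, len(y) - 2)
    denom = cdf[idx + 1] - cdf[idx]
    t = np.where(denom > 0, (u - cdf[idx]) / np.where(denom > 0, denom, 1.0), 0.0)
    vals = y[idx] + t * (y[idx + 1] - y[idx])
    return vals if size is not None else float(vals[0])


def sample_conditional_in_range(
    kde: Kde2D,
    d_prev: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw from f(d_new | d_prev) restricted to the interval [lo, hi].

    Used when geometry bounds the reachable distances: the conditional slice
    is renormalized over the feasible band. Raises :class:`SamplingError`
    when the band carries (essentially) no probability mass."""
    if hi <= lo:
        raise SamplingError("empty feasible interval")
    y, cdf = slice_cdf(kde, d_prev)
    c_lo = float(np.interp(lo, y, cdf, left=0.0, right=1.0))
    c_hi = float(np.interp(hi, y, cdf, left=0.0, right=1.0))
    if c_hi - c_lo < 1e-9:
        raise SamplingError(
            f"conditional slice has no mass in [{lo:.2f}, {hi:.2f}] at d_prev={d_prev:.2f}"
        )
    u = c_lo + (c_hi - c_lo) * rng.random(size if size is not None else 1)
    idx = np.clip(np.searchsorted(cdf, u, side="right") - 1, 0, len(y) - 2)
    denom = cdf[idx + 1] - cdf[idx]
    t = np.where(denom > 0, (u - cdf[idx]) / np.where(denom > 0, denom, 1.0), 0.0)
    vals = np.clip(y[idx] + t * (y[idx + 1] - y[idx]), lo, hi)
    return vals if size is not None else float(vals[0])


def conditional_slices(kde: Kde2D, d_prev: np.ndarray) -> np.ndarray:
    """Row-wise conditional slices: one unnormalized d_new density per query
    d_prev (zero rows for queries outside the domain)."""
    d_prev = np.asarray(d_prev, dtype=float)
    x = kde.x_nodes
    i = np.clip(np.searchsorted(x, d_prev) - 1, 0, len(x) - 2)
    tx = np.clip((d_prev - x[i]) / (x[i + 1] - x[i]), 0.0, 1.0)
    rows = (1.0 - tx)[:, None] * kde.grid[i, :] + tx[:, None] * kde.grid[i + 1, :]
    outside = (d_prev < x[0]) | (d_prev > x[-1])
    rows[outside] = 0.0
    return rows


def sample_conditional_in_range_rows(
    kde: Kde2D,
    d_prev: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`sample_conditional_in_range` with per-row d_prev and
    band. Rows whose band carries no conditional mass fall back to a uniform
    draw over the band. Returns (values, had_mass)."""
    d_prev = np.asarray(d_prev, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    m = len(d_prev)
    y = kde.y_nodes
    dy = y[1] - y[0]
    f = conditional_slices(kde, d_prev)
    seg = 0.5 * (f[:, 1:] + f[:, :-1]) * dy
    cdf = np.concatenate([np.zeros((m, 1)), np.cumsum(seg, axis=1)], axis=1)
    total = cdf[:, -1]

    def interp_cdf(q):
        i = np.clip(np.searchsorted(y, q) - 1, 0, len(y) - 2)
        t = np.clip((q - y[i]) / dy, 0.0, 1.0)
        r = np.arange(m)
        return cdf[r, i] + t * (cdf[r, i + 1] - cdf[r, i])

    c_lo = interp_cdf(np.clip(lo, y[0], y[-1]))
    c_hi = interp_cdf(np.clip(hi, y[0], y[-1]))
    c_lo = np.where(lo <= y[0], 0.0, c_lo)
    c_hi = np.where(hi >= y[-1], total, c_hi)
    mass = c_hi - c_lo
    had_mass = (total > 0) & (mass > 1e-12 * np.maximum(total, 1.0))

    u = c_lo + mass * rng.random(m)
    idx = np.clip((cdf < u[:, None]).sum(axis=1) - 1, 0, len(y) - 2)
    r = np.arange(m)
    denom = cdf[r, idx + 1] - cdf[r, idx]
    t = np.where(denom > 0, (u - cdf[r, idx]) / np.where(denom > 0, denom, 1.0), 0.0)
    vals = y[idx] + t * dy
    uni = lo + (hi - lo) * rng.random(m)
    vals = np.where(had_mass, vals, uni)
    return np.clip(vals, lo, hi), had_mass


def sample_marginal(kde: Kde2D, rng: np.random.Generator) -> float:
    """Fallback draw from the marginal of d_new (used when a conditional slice
    is empty because d_prev fell far outside the fitted domain)."""
    f = np.trapezoid(kde.grid, kde.x_nodes, axis=0)
    seg = 0.5 * (f[1:] + f[:-1]) * np.diff(kde.y_nodes)
    total = seg.sum()
    cdf = np.concatenate([[0.0], np.cumsum(seg)]) / total
    cdf[-1] = 1.0
    u = rng.random()
    idx = int(np.clip(np.searchsorted(cdf, u, side="right") - 1, 0, len(kde.y_nodes) - 2))
    denom = cdf[idx + 1] - cdf[idx]
    t = 0.0 if denom <= 0 else (u - cdf[idx]) / denom
    return float(kde.y_nodes[idx] + t * (kde.y_nodes[idx + 1] - kde.y_nodes[idx]))


@dataclass
class DihedralTable:
    """(phi, psi) frequency table for one residue type.

    Bins are ``bin_width`` degrees wide, spanning [-180, 180) on both axes.
    Log-probabilities are floored by a pseudocount so unseen bins stay finite.
    """

    residue_type: str
    bin_width: float = DEFAULT_PHI_PSI_BIN
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    pseudocount_fraction: float = DEFAULT_PSEUDOCOUNT_FRACTION

    def __post_init__(self) -> None:
        self.n_bins = int(round(360.0 / self.bin_width))
        if abs(self.n_bins * self.bin_width - 360.0) > 1e-9:
            raise ValueError("bin width must divide 360")
        if self.counts is None:
            self.counts = np.zeros((self.n_bins, self.n_bins))
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_bins, self.n_bins):
            raise ValueError("counts shape mismatch")

    def _bin(self, angle) -> np.ndarray:
        a = wrap_degrees(angle)
        return np.clip(((a + 180.0) / self.bin_width).astype(int), 0, self.n_bins - 1)

    def add(self, phi: float, psi: float, weight: float = 1.0) -> None:
        self.counts[self._bin(phi), self._bin(psi)] += weight

    def log_prob(self, phi, psi) -> np.ndarray | float:
        """Log of the normalized (count + pseudocount) mass of the (phi, psi)
        bin; finite for any input."""
        total = self.counts.sum()
        eps = self.pseudocount_fraction * max(total, 1.0)
        z = total + eps * self.counts.size
        scalar = np.isscalar(phi) and np.isscalar(psi)
        p = (self.counts[self._bin(np.atleast_1d(phi)), self._bin(np.atleast_1d(psi))] + eps) / z
        out = np.log(p)
        return float(out[0]) if scalar else out


def dihedral_log_prob(table: DihedralTable, phi: float, psi: float) -> float:
    return float(table.log_prob(phi, psi))


def select_k_trials(
    phis: np.ndarray,
    psis: np.ndarray,
    table: DihedralTable,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of ``k`` distinct trials drawn without replacement with
    probability proportional to the empirical (phi, psi) bin mass."""
    m = len(phis)
    if not (1 <= k <= m):
        raise ValueError(f"need 1 <= k <= m, got k={k}, m={m}")
    if k == m:
        return np.arange(m)
    logp = np.asarray(table.log_prob(np.asarray(phis), np.asarray(psis)))
    w = np.exp(logp - logp.max())
    p = w / w.sum()
    return rng.choice(m, size=k, replace=False, p=p)


@dataclass
class ChiTable:
    """Side-chain rotamer table for one residue type.

    Chi vectors are discretized into ``bin_width``-degree bins per DOF; only
    populated bins are retained. Each bin stores its observation count and the
    running mean chi vector of its members, which is what gets sampled.
    """

    residue_type: str
    n_chi: int
    bin_width: float = DEFAULT_PHI_PSI_BIN
    bins: dict = field(default_factory=dict)  # key tuple -> [count, mean (n_chi,)]

    def _key(self, chi) -> tuple:
        a = wrap_degrees(np.asarray(chi, dtype=float))
        return tuple(int(np.clip((v + 180.0) // self.bin_width, 0, 360.0 / self.bin_width - 1)) for v in a)

    def add(self, chi) -> None:
        chi = np.asarray(chi, dtype=float)[: self.n_chi]
        if len(chi) != self.n_chi:
            raise ValueError("chi vector length mismatch")
        key = self._key(chi)
        if key not in self.bins:
            self.bins[key] = [0, np.zeros(self.n_chi)]
        entry = self.bins[key]
        entry[0] += 1
        entry[1] += (chi - entry[1]) / entry[0]

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw chi vectors: a populated bin proportional to its count, then
        that bin's mean chi vector."""
        if not self.bins:
            raise SamplingError(f"no rotamer observations for {self.residue_type}")
        keys = sorted(self.bins)
        counts = np.array([self.bins[k][0] for k in keys], dtype=float)
        idx = rng.choice(len(keys), size=size, p=counts / counts.sum())
        return np.array([self.bins[keys[i]][1] for i in idx])
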