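"""Potentials of mean force from umbrella-sampling windows via WHAM.

Each window holds reaction-coordinate samples (nm) collected under a
harmonic bias w_i(x) = k_i/2 (x - c_i)^2 (kJ/mol). The weighted histogram
analysis method solves self-consistently for the unbiased distribution

    P(x_b) = sum_i n_i(b) / sum_j N_j exp(-beta [w_j(x_b) - F_j])
    exp(-beta F_j) = sum_b P(x_b) exp(-beta w_j(x_b))

and the profile is W = -kT ln P, anchored to zero at the largest-x
populated bin — the ligand-in-bulk-solvent plateau. Statistical errors
come from bootstrap resampling of each window's samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "KB",
    "UmbrellaWindow",
    "PMFProfile",
    "OverlapReport",
    "WindowOverlapError",
    "wham",
    "bootstrap_pmf",
    "window_overlap",
    "WHAM",
    "load_umbrella_windows",
]

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083145


class WindowOverlapError(ValueError):
    pass


@dataclass
class UmbrellaWindow:
    """One biased window: center (nm), force constant (kJ/mol/nm^2), samples."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    def bias(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFProfile:
    xi: np.ndarray  # populated bin centers, nm
    w: np.ndarray  # free energy, kJ/mol, anchored
    se: np.ndarray | None  # bootstrap standard error per bin
    window_free_energies: np.ndarray
    temperature: float
    converged: bool
    n_iter: int
    bin_width: float

    def to_frame(self):
        import pandas as pd

        out = pd.DataFrame({"xi_nm": self.xi, "w_kj_mol": self.w})
        if self.se is not None:
            out["se_kj_mol"] = self.se
        return out


def _histograms(
    windows: Sequence[UmbrellaWindow], edges: np.ndarray
) -> np.ndarray:
    return np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])


def _make_edges(windows: Sequence[UmbrellaWindow], bin_width: float) -> np.ndarray:
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    return lo + bin_width * np.arange(n_bins + 1)


def _check_chain(windows: Sequence[UmbrellaWindow], edges: np.ndarray) -> None:
    if len(windows) < 2:
        return
    order = np.argsort([w.center for w in windows])
    hists = _histograms(windows, edges).astype(float)
    for a, b in zip(order[:-1], order[1:]):
        pa = hists[a] / hists[a].sum()
        pb = hists[b] / hists[b].sum()
        if np.minimum(pa, pb).sum() == 0.0:
            raise WindowOverlapError(
                f"no histogram overlap between windows centred at "
                f"{windows[a].center:g} and {windows[b].center:g} nm"
            )


def _wham_core(
    windows: Sequence[UmbrellaWindow],
    edges: np.ndarray,
    temperature: float,
    tol: float,
    max_iter: int,
    anchor: str,
) -> PMFProfile:
    beta = 1.0 / (KB * temperature)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ib = _histograms(windows, edges).astype(float)  # (n_win, n_bins)
    populated = n_ib.sum(axis=0) > 0
    N_i = n_ib.sum(axis=1)  # per-window totals
    w_ib = np.stack([w.bias(centers) for w in windows])  # (n_win, n_bins)
    log_num = np.where(populated, np.log(np.where(populated, n_ib.sum(axis=0), 1.0)), -np.inf)
    log_N = np.log(N_i)
    bf = np.zeros(len(windows))  # beta * F_i
    converged = False
    it = 0
    for it in range(1, int(max_iter) + 1):
        # log P_b = log(sum_i n_ib) - logsumexp_j [log N_j + bF_j - b w_jb]
        log_den = logsumexp(log_N[:, None] + bf[:, None] - beta * w_ib, axis=0)
        log_P = log_num - log_den
        log_P -= logsumexp(log_P[populated])
        bf_new = -logsumexp(log_P[None, populated] - beta * w_ib[:, populated], axis=1)
        bf_new -= bf_new[0]
        delta = np.max(np.abs(bf_new - bf)) / beta  # kJ/mol
        bf = bf_new
        if delta < tol:
            converged = True
            break
    W = np.where(populated, -log_P / beta, np.nan)
    xi = centers[populated]
    w = W[populated]
    if anchor == "bulk":
        w = w - w[-1]  # largest-xi populated bin
    elif anchor == "min":
        w = w - w.min()
    elif anchor == "none":
        pass
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return PMFProfile(
        xi=xi,
        w=w,
        se=None,
        window_free_energies=bf / beta,
        temperature=temperature,
        converged=converged,
        n_iter=it,
        bin_width=float(edges[1] - edges[0]) if len(edges) > 1 else 0.0,
    )


def wham(
    windows: Iterable[UmbrellaWindow],
    temperature: float = 310.0,
    bin_width: float = 0.02,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: str = "bulk",
) -> PMFProfile:
    """Self-consistent WHAM estimate of the PMF from umbrella windows.

    Non-overlapping adjacent windows raise :class:`WindowOverlapError`
    naming the gap; failure to converge within ``max_iter`` is reported
    through the profile's ``converged`` flag, not an exception.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    edges = _make_edges(windows, bin_width)
    _check_chain(windows, edges)
    profile = _wham_core(windows, edges, temperature, tol, max_iter, anchor)
    if not profile.converged:
        warnings.warn(
            f"WHAM did not converge within {max_iter} iterations", RuntimeWarning
        )
    return profile


def bootstrap_pmf(
    windows: Iterable[UmbrellaWindow],
    n_boot: int = 100,
    seed: int | None = None,
    temperature: float = 310.0,
    bin_width: float = 0.02,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: str = "bulk",
) -> PMFProfile:
    """Point-estimate PMF with per-bin bootstrap standard errors.

    Each replicate resamples every window's samples with replacement and
    re-runs WHAM on the point estimate's bin grid. Because the profile is
    defined only up to an additive constant, each replicate is aligned to
    the point estimate by its mean offset over common bins before the
    per-bin standard deviation is taken; otherwise the bands would mostly
    measure the sampling noise of whichever bin happens to be the anchor.
    A seed is mandatory so the error bands are reproducible.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    windows = list(windows)
    edges = _make_edges(windows, bin_width)
    _check_chain(windows, edges)
    point = _wham_core(windows, edges, temperature, tol, max_iter, anchor)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = np.isin(np.round(centers, 12), np.round(point.xi, 12))
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, point.xi.size), np.nan)
    for b in range(n_boot):
        resampled = [
            UmbrellaWindow(
                center=w.center,
                force_constant=w.force_constant,
                samples=rng.choice(w.samples, size=w.n, replace=True),
            )
            for w in windows
        ]
        prof_b = _wham_core(resampled, edges, temperature, tol, max_iter, anchor)
        full = np.full(centers.size, np.nan)
        mask = np.isin(np.round(centers, 12), np.round(prof_b.xi, 12))
        full[mask] = prof_b.w
        rep = full[keep]
        offset = np.nanmean(rep - point.w)
        boots[b] = rep - (offset if np.isfinite(offset) else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(boots, axis=0, ddof=1)
    point.se = se
    return point


@dataclass
class OverlapReport:
    overlap: np.ndarray  # pairwise, ordered by window center
    centers: np.ndarray
    warnings: list[str]


def window_overlap(
    windows: Iterable[UmbrellaWindow],
    bin_width: float = 0.02,
    threshold: float = 0.05,
) -> OverlapReport:
    """Pairwise histogram overlap sum_b min(p_i(b), p_j(b)).

    Adjacent pairs (by center) below ``threshold`` produce warnings —
    the diagnostic used to decide whether intermediate windows are needed.
    """
    windows = sorted(windows, key=lambda w: w.center)
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    edges = _make_edges(windows, bin_width)
    hists = _histograms(windows, edges).astype(float)
    p = hists / hists.sum(axis=1, keepdims=True)
    n = len(windows)
    overlap = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            o = float(np.minimum(p[i], p[j]).sum())
            overlap[i, j] = overlap[j, i] = o
    msgs = []
    for i in range(n - 1):
        if overlap[i, i + 1] < threshold:
            msgs.append(
                f"overlap {overlap[i, i + 1]:.3f} between windows at "
                f"{windows[i].center:g} and {windows[i + 1].center:g} nm is below "
                f"{threshold:g}; consider an intermediate window"
            )
    return OverlapReport(
        overlap=overlap,
        centers=np.array([w.center for w in windows]),
        warnings=msgs,
    )


class WHAM(BaseEstimator):
    """Estimator wrapper around :func:`wham` / :func:`bootstrap_pmf`.

    Parameters mirror the functional interface; ``n_boot=0`` skips the
    bootstrap. After ``fit`` the profile is available as ``xi_``, ``pmf_``,
    ``se_``, ``window_free_energies_``, ``converged_`` and ``n_iter_``.
    """

    def __init__(
        self,
        temperature: float = 310.0,
        bin_width: float = 0.02,
        tol: float = 1e-6,
        max_iter: int = 100_000,
        anchor: str = "bulk",
        n_boot: int = 0,
        random_state: int | None = None,
    ):
        self.temperature = temperature
        self.bin_width = bin_width
        self.tol = tol
        self.max_iter = max_iter
        self.anchor = anchor
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, windows: Iterable[UmbrellaWindow], y=None):
        windows = list(windows)
        if self.n_boot:
            profile = bootstrap_pmf(
                windows,
                n_boot=self.n_boot,
                seed=self.random_state,
                temperature=self.temperature,
                bin_width=self.bin_width,
                tol=self.tol,
                max_iter=self.max_iter,
                anchor=self.anchor,
            )
        else:
            profile = wham(
                windows,
                temperature=self.temperature,
                bin_width=self.bin_width,
                tol=self.tol,
                max_iter=self.max_iter,
                anchor=self.anchor,
            )
        self.profile_ = profile
        self.xi_ = profile.xi
        self.pmf_ = profile.w
        self.se_ = profile.se
        self.window_free_energies_ = profile.window_free_energies
        self.converged_ = profile.converged
        self.n_iter_ = profile.n_iter
        return self


def load_umbrella_windows(
    metadata, directory=None, equilibration_fraction: float = 0.10
) -> list[UmbrellaWindow]:
    """Load windows from per-window two-column (time, xi) text files.

    ``metadata`` is a CSV with columns file, center, force_constant. The
    first ``equilibration_fraction`` of each series is dropped, matching
    the convention of discarding the initial equilibration stretch of each
    window (10% by default).
    """
    import pandas as pd
    from pathlib import Path

    meta = pd.read_csv(metadata)
    required = {"file", "center", "force_constant"}
    if required - set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    base = Path(directory) if directory is not None else Path(metadata).parent
    windows = []
    for row in meta.itertuples():
        data = np.loadtxt(base / row.file)
        xi = np.atleast_2d(data)[:, 1]
        n_skip = int(np.floor(equilibration_fraction * xi.size))
        windows.append(
            UmbrellaWindow(
                center=float(row.center),
                force_constant=float(row.force_constant),
                samples=xi[n_skip:],
            )
        )
    return windows
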