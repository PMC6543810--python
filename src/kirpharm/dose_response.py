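"""Fractional block, Hill-equation IC50 fitting and rectification analysis.

The fit target is fractional block versus drug concentration,

    B([D]) = ([D]/IC50)^h / (1 + ([D]/IC50)^h),

with B(0) = 0 and B(inf) = 1 fixed — currents are normalised to the
control trace, so the asymptotes are not free parameters. Drug-induced
rectification is stronger inhibition of outward (+50 mV) than inward
(-80 mV) current, assessed by a paired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "hill",
    "fractional_block",
    "DoseResponseTable",
    "HillFit",
    "HillCurve",
    "fit_hill",
    "RectificationResult",
    "rectification",
    "NonIdentifiableError",
]


class NonIdentifiableError(ValueError):
    pass


def hill(concentration, ic50: float, h: float):
    """Fractional block of the Hill model (0 at zero dose, 1 at saturation)."""
    c = np.asarray(concentration, dtype=float)
    x = (c / ic50) ** h
    return x / (1.0 + x)


def fractional_block(control_current: float, drug_current: float) -> float:
    """block = 1 - I_drug / I_control."""
    if control_current == 0:
        raise ValueError("control current must be non-zero")
    return 1.0 - drug_current / control_current


@dataclass
class DoseResponseTable:
    """Replicate fractional-block measurements for one drug and branch."""

    drug: str
    branch: str  # "outward" (+50 mV) or "inward" (-80 mV)
    data: pd.DataFrame  # columns: conc_uM, block, replicate_id

    def __post_init__(self) -> None:
        if self.branch not in ("outward", "inward"):
            raise ValueError("branch must be 'outward' or 'inward'")
        required = {"conc_uM", "block"}
        if required - set(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        conc = self.data["conc_uM"].to_numpy(dtype=float)
        block = self.data["block"].to_numpy(dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(block < -0.05) or np.any(block > 1.05):
            raise ValueError("block values outside the [-0.05, 1.05] guard band")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["conc_uM"].unique())

    def means(self) -> pd.DataFrame:
        g = self.data.groupby("conc_uM")["block"]
        out = pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})
        return out.sort_index()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "branch", self.branch)
        out.insert(0, "drug", self.drug)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, source, drug: str | None = None, branch: str | None = None):
        df = pd.read_csv(source)
        if drug is not None:
            df = df[df["drug"] == drug]
        if branch is not None:
            df = df[df["branch"] == branch]
        if not len(df):
            raise ValueError("no rows after drug/branch selection")
        return cls(
            drug=str(df["drug"].iloc[0]) if "drug" in df else (drug or ""),
            branch=str(df["branch"].iloc[0]) if "branch" in df else (branch or "outward"),
            data=df[[c for c in ("conc_uM", "block", "replicate_id") if c in df]].reset_index(
                drop=True
            ),
        )


@dataclass
class HillFit:
    ic50: float
    h: float
    ic50_se: float
    h_se: float
    rss: float
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        if self.converged:
            if self.ic50 <= 0 or self.h <= 0:
                raise ValueError("fitted IC50 and h must be positive")


class HillCurve(BaseEstimator, RegressorMixin):
    """Least-squares Hill-equation fit of fractional block vs concentration.

    Parameters
    ----------
    ic50_bounds, h_bounds:
        Box constraints for the optimiser. The Hill coefficient is capped
        at 5 — steeper curves than that are not physiological for single
        binding reactions.
    init:
        "geometric" starts IC50 at the geometric mean of the doses with
        h = 1; a (ic50, h) tuple overrides.

    Fitted attributes: ``ic50_``, ``h_``, ``ic50_se_``, ``h_se_``,
    ``rss_``, ``converged_``.
    """

    def __init__(
        self,
        init="geometric",
        ic50_bounds: tuple[float, float] = (1e-9, 1e4),
        h_bounds: tuple[float, float] = (1e-9, 5.0),
    ):
        self.init = init
        self.ic50_bounds = ic50_bounds
        self.h_bounds = h_bounds

    def fit(self, X, y, sample_weight_sigma=None):
        """Fit on concentrations X (uM) and block values y in [0, 1].

        ``sample_weight_sigma`` are per-point standard errors used as
        curve_fit sigma (relative weighting); None fits unweighted.
        """
        C = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if C.size != y.size:
            raise ValueError("X and y must have equal length")
        if np.unique(C).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if y.max() < 1e-9 or y.min() > 1 - 1e-9:
            raise NonIdentifiableError(
                "responses are all-zero or all-one; IC50 is not identifiable"
            )
        if self.init == "geometric":
            p0 = (float(np.exp(np.mean(np.log(C)))), 1.0)
        else:
            p0 = tuple(float(v) for v in self.init)
        lb = (self.ic50_bounds[0], self.h_bounds[0])
        ub = (self.ic50_bounds[1], self.h_bounds[1])
        sigma = None
        if sample_weight_sigma is not None:
            sigma = np.asarray(sample_weight_sigma, dtype=float).ravel()
            if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
                sigma = None  # degenerate weights: fall back to unweighted
        try:
            popt, pcov = optimize.curve_fit(
                hill, C, y, p0=p0, bounds=(lb, ub), sigma=sigma, maxfev=20000
            )
            converged = bool(np.all(np.isfinite(popt)))
        except (RuntimeError, optimize.OptimizeWarning):
            popt = np.array(p0)
            pcov = np.full((2, 2), np.nan)
            converged = False
        ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
        self.ic50_ = float(popt[0])
        self.h_ = float(popt[1])
        self.ic50_se_ = float(ses[0])
        self.h_se_ = float(ses[1])
        self.rss_ = float(np.sum((hill(C, *popt) - y) ** 2))
        self.converged_ = converged
        self.n_obs_ = int(C.size)
        return self

    def predict(self, X):
        return hill(np.asarray(X, dtype=float).ravel(), self.ic50_, self.h_)


def fit_hill(
    table: DoseResponseTable,
    init="geometric",
    weighting: str = "sem",
) -> HillFit:
    """Fit the Hill equation to a dose-response table.

    weighting:
        "sem" (default): fit per-dose means weighted by their standard
        errors (falls back to unweighted when any SEM is zero/undefined);
        "none": unweighted fit on per-dose means;
        "replicates": fit all replicate points unweighted.
    """
    if table.concentrations.size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    est = HillCurve(init=init)
    if weighting == "replicates":
        est.fit(table.data["conc_uM"], table.data["block"])
    elif weighting in ("sem", "none"):
        m = table.means()
        sigma = None
        if weighting == "sem":
            sem = m["sem"].to_numpy(dtype=float)
            if np.all(np.isfinite(sem)) and np.all(sem > 0):
                sigma = sem
        est.fit(m.index.to_numpy(), m["mean"].to_numpy(), sample_weight_sigma=sigma)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return HillFit(
        ic50=est.ic50_,
        h=est.h_,
        ic50_se=est.ic50_se_,
        h_se=est.h_se_,
        rss=est.rss_,
        converged=est.converged_,
        n_obs=est.n_obs_,
    )


@dataclass
class RectificationResult:
    index: float  # mean outward block / mean inward block
    t_statistic: float
    p_value: float
    rectifying: bool
    n: int


def rectification(
    block_outward: Sequence[float],
    block_inward: Sequence[float],
    alpha: float = 0.05,
) -> RectificationResult:
    """Paired comparison of outward vs inward fractional block.

    The index is mean(outward)/mean(inward); the paired two-tailed t-test
    asks whether outward block exceeds inward block beyond chance. Zero
    mean inward block gives an infinite index (guarded); identical paired
    samples degenerate to t = 0, p = 1, non-rectifying.
    """
    out = np.asarray(block_outward, dtype=float)
    inw = np.asarray(block_inward, dtype=float)
    if out.shape != inw.shape:
        raise ValueError("paired samples must have equal length")
    if out.size < 2:
        raise ValueError("paired test requires n >= 2")
    mean_in = inw.mean()
    index = float("inf") if mean_in == 0 else float(out.mean() / mean_in)
    diffs = out - inw
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(diffs.mean()) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(out, inw)
    rectifying = bool(index > 1 and p < alpha)
    return RectificationResult(
        index=index,
        t_statistic=float(t),
        p_value=float(p),
        rectifying=rectifying,
        n=int(out.size),
    )
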