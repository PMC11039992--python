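"""One-site specific-binding model fitting for EMSA titrations.

The model is y = Bmax * x / (Kd + x) with free ligand approximated by
total protein concentration (protein in vast excess over the labelled
probe).  Both parameters are fitted by bounded nonlinear least squares
over all pooled observations; a fixed-Bmax single-parameter mode is also
available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InvalidArgumentError

__all__ = [
    "BindingObservation",
    "BindingDataset",
    "KdEstimate",
    "predict_fraction_bound",
    "fit_one_site",
    "affinity_ratio",
]


@dataclass(frozen=True)
class BindingObservation:
    """One (protein concentration, fraction bound) measurement."""

    concentration: float  # uM
    fraction_bound: float
    replicate_id: str = "r1"

    def __post_init__(self):
        if self.concentration <= 0:
            raise InvalidArgumentError(
                f"concentration must be > 0, got {self.concentration}"
            )
        if not math.isfinite(self.fraction_bound):
            raise InvalidArgumentError("fraction_bound must be finite")


@dataclass
class BindingDataset:
    """All observations from one titration series."""

    observations: list[BindingObservation]
    rna_label: str = ""
    protein_label: str = ""

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([o.concentration for o in self.observations])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([o.fraction_bound for o in self.observations])

    def n_distinct_concentrations(self) -> int:
        return len(set(o.concentration for o in self.observations))

    def replicate_means(self) -> "BindingDataset":
        """Collapse replicates to per-concentration means."""
        by_conc: dict[float, list[float]] = {}
        for o in self.observations:
            by_conc.setdefault(o.concentration, []).append(o.fraction_bound)
        obs = [
            BindingObservation(c, float(np.mean(ys)), "mean")
            for c, ys in sorted(by_conc.items())
        ]
        return BindingDataset(obs, self.rna_label, self.protein_label)


@dataclass
class KdEstimate:
    """Fitted one-site parameters with curvature-based standard errors."""

    kd: float
    bmax: float
    kd_se: float
    bmax_se: float
    rss: float
    n_obs: int
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kd": self.kd,
            "bmax": self.bmax,
            "kd_se": self.kd_se,
            "bmax_se": self.bmax_se,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def predict_fraction_bound(x, kd: float, bmax: float):
    """One-site specific binding: ``bmax * x / (kd + x)``.

    Strictly increasing in x, bounded above by bmax, and equal to
    bmax/2 at x = kd.
    """
    if kd <= 0:
        raise InvalidArgumentError(f"kd must be > 0, got {kd}")
    if bmax <= 0:
        raise InvalidArgumentError(f"bmax must be > 0, got {bmax}")
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise InvalidArgumentError("concentrations must be >= 0")
    out = bmax * x / (kd + x)
    return float(out) if out.ndim == 0 else out


def fit_one_site(
    data: BindingDataset,
    init: tuple[float, float] | None = None,
    fix_bmax: float | None = None,
) -> KdEstimate:
    """Fit Kd (and Bmax) by nonlinear least squares on pooled observations.

    Default initialization: ``bmax0`` = max observed fraction bound,
    ``kd0`` = the concentration whose observed response is nearest
    ``bmax0 / 2``.  Parameters are constrained positive by bounded
    optimization; standard errors come from the Gauss-Newton
    approximation to the curvature at the optimum.

    Parameters
    ----------
    data
        Titration observations; at least 4 distinct concentrations.
    init
        Optional (kd0, bmax0) override.
    fix_bmax
        If given, Bmax is held at this value and only Kd is fitted
        (its SE is reported as 0).

    Raises
    ------
    InvalidArgumentError
        Fewer than 4 distinct concentrations, or no observations.
    FitError
        Optimizer failure or an unidentifiable (flat) response.
    """
    if not data.observations:
        raise InvalidArgumentError("empty binding dataset")
    if data.n_distinct_concentrations() < 4:
        raise InvalidArgumentError(
            f"need >= 4 distinct concentrations, got {data.n_distinct_concentrations()}"
        )
    x = data.concentrations
    y = data.fractions
    if x.max() / x.min() < 10:
        warnings.warn(
            "concentration range spans less than 10x; Kd may be poorly constrained",
            stacklevel=2,
        )
    if np.ptp(y) == 0:
        raise FitError(
            "fraction bound is constant across concentrations; "
            "Kd/Bmax are unidentifiable",
            diagnostics={"y_value": float(y[0])},
        )

    if init is not None:
        kd0, bmax0 = init
    else:
        bmax0 = float(y.max())
        if bmax0 <= 0:
            bmax0 = 1.0
        kd0 = float(x[np.argmin(np.abs(y - bmax0 / 2.0))])
    kd0 = max(kd0, 1e-9)
    bmax0 = max(bmax0, 1e-9)

    if fix_bmax is not None:
        def residuals(theta):
            return fix_bmax * x / (theta[0] + x) - y
        theta0 = np.array([kd0])
        bounds = ([1e-12], [np.inf])
    else:
        def residuals(theta):
            return theta[1] * x / (theta[0] + x) - y
        theta0 = np.array([kd0, bmax0])
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])

    result = least_squares(
        residuals, theta0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not result.success:
        raise FitError(
            f"one-site fit did not converge: {result.message}",
            diagnostics={"status": result.status, "message": result.message},
        )

    rss = float(result.fun @ result.fun)
    n = len(x)
    p = len(theta0)
    # SEs from the Gauss-Newton curvature: cov = s^2 (J^T J)^-1.
    J = result.jac
    dof = max(n - p, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(p, np.nan)

    if fix_bmax is not None:
        kd, bmax = float(result.x[0]), float(fix_bmax)
        kd_se, bmax_se = float(ses[0]), 0.0
    else:
        kd, bmax = float(result.x[0]), float(result.x[1])
        kd_se, bmax_se = float(ses[0]), float(ses[1])

    return KdEstimate(
        kd=kd,
        bmax=bmax,
        kd_se=kd_se,
        bmax_se=bmax_se,
        rss=rss,
        n_obs=n,
        converged=True,
        diagnostics={
            "optimality": float(result.optimality),
            "nfev": int(result.nfev),
            "init": {"kd0": kd0, "bmax0": bmax0},
        },
    )


def fit_per_replicate(data: BindingDataset, **kwargs) -> dict[str, KdEstimate]:
    """Fit each replicate separately (alternative to pooled fitting)."""
    by_rep: dict[str, list[BindingObservation]] = {}
    for o in data.observations:
        by_rep.setdefault(o.replicate_id, []).append(o)
    return {
        rep: fit_one_site(BindingDataset(obs, data.rna_label, data.protein_label), **kwargs)
        for rep, obs in sorted(by_rep.items())
    }


def affinity_ratio(a: KdEstimate, b: KdEstimate) -> tuple[float, float]:
    """Kd ratio a/b with delta-method standard error.

    A ratio > 1 means ``a`` binds more weakly (larger Kd).  The SE
    propagates the two Kd SEs assuming independence:
    se = ratio * sqrt((se_a/kd_a)^2 + (se_b/kd_b)^2).
    """
    ratio = a.kd / b.kd
    se = ratio * math.sqrt((a.kd_se / a.kd) ** 2 + (b.kd_se / b.kd) ** 2)
    return ratio, se
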