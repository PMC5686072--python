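"""Chemical-shift-perturbation analysis and fast-exchange K_D fitting.

In the fast-exchange regime a nucleus shows a single resonance at the
population-weighted average of its free and bound positions, so the
observed perturbation at each titration point is

    ddelta_obs = ddelta_max * f_b(P_t, L_t, K_D)

with f_b the bound fraction from the single-site mass-action quadratic

    f_b = ((P_t + L_t + K_D) - sqrt((P_t + L_t + K_D)^2 - 4 P_t L_t)) / (2 P_t).

Fitting ddelta_obs against the ligand schedule yields K_D and ddelta_max.
Concentrations are mM and shifts ppm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import spearmanr

__all__ = [
    "ShiftRecord",
    "TitrationSeries",
    "BindingFit",
    "combined_csp",
    "fraction_bound",
    "predict_csp",
    "fit_kd",
    "csp_profile_compare",
]

#: Multi-start grid over K_D (mM) used to escape local minima.
KD_STARTS = (0.1, 1.0, 10.0, 100.0)
KD_UPPER = 1e6  # mM; fits pinned near this bound are non-identifiable


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned amide shift at one titration point."""

    residue_number: int
    residue_type: str
    atom: str  # "H" or "N"
    shift: float  # ppm
    titration_point: int  # 0 = free protein

    def __post_init__(self) -> None:
        if self.atom not in ("H", "N"):
            raise ValueError("atom must be 'H' or 'N'")
        if not math.isfinite(self.shift):
            raise ValueError("shift must be finite")
        if self.titration_point < 0:
            raise ValueError("titration_point must be >= 0")


@dataclass
class TitrationSeries:
    """Per-residue combined CSPs across a ligand titration.

    ``csp`` has shape (n_residues, n_points) with the first column (the
    ligand-free reference) exactly zero.
    """

    protein_total: float  # mM
    ligand_totals: np.ndarray  # mM, ascending, first entry 0
    csp: np.ndarray  # ppm
    residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.csp = np.atleast_2d(np.asarray(self.csp, dtype=float))
        if self.protein_total <= 0:
            raise ValueError("protein_total must be positive")
        if self.ligand_totals[0] != 0:
            raise ValueError("first titration point must be ligand-free (L_t = 0)")
        if np.any(np.diff(self.ligand_totals) <= 0):
            raise ValueError("ligand_totals must be strictly ascending")
        if self.csp.shape[1] != len(self.ligand_totals):
            raise ValueError("csp columns must align with ligand_totals")
        if np.any(self.csp[:, 0] != 0):
            raise ValueError("CSP at the ligand-free point must be 0")
        if not self.residues:
            self.residues = list(range(self.csp.shape[0]))
        if len(self.residues) != self.csp.shape[0]:
            raise ValueError("residue list must align with csp rows")

    @property
    def n_points(self) -> int:
        return len(self.ligand_totals)


@dataclass
class BindingFit:
    """Fitted single-site fast-exchange binding parameters.

    ``dmax`` (and ``se_dmax``) are arrays aligned with the fitted residue
    list (length 1 for a single-residue fit).
    """

    kd: float  # mM
    dmax: np.ndarray  # ppm, per residue
    se_kd: float
    se_dmax: np.ndarray
    rss: float
    converged: bool
    residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dmax = np.atleast_1d(np.asarray(self.dmax, dtype=float))
        self.se_dmax = np.atleast_1d(np.asarray(self.se_dmax, dtype=float))
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.converged and (self.se_kd < 0 or np.any(self.se_dmax < 0)):
            raise ValueError("standard errors must be >= 0 for a converged fit")


def combined_csp(delta_h: float, delta_n: float, alpha: float = 0.14) -> float:
    """Combined amide CSP: sqrt(ddH^2 + (alpha * ddN)^2).

    ``alpha`` down-weights the nitrogen shift to the proton scale
    (standard amide weighting, default 0.14).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return math.sqrt(delta_h**2 + (alpha * delta_n) ** 2)


def fraction_bound(pt, lt, kd):
    """Bound protein fraction for single-site binding (quadratic solution).

    Takes the physically meaningful "minus" branch of the mass-action
    quadratic; the "plus" branch would exceed the total protein. Accepts
    scalars or arrays for ``lt``.
    """
    pt = float(pt)
    kd = float(kd)
    if pt <= 0 or kd <= 0:
        raise ValueError("pt and kd must be positive")
    lt_arr = np.asarray(lt, dtype=float)
    if np.any(lt_arr < 0):
        raise ValueError("lt must be >= 0")
    s = pt + lt_arr + kd
    disc = s * s - 4.0 * pt * lt_arr
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * pt)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def predict_csp(dmax: float, fb) -> float | np.ndarray:
    """Observed fast-exchange CSP: population-weighted average dmax * f_b."""
    fb_arr = np.asarray(fb, dtype=float)
    if np.any((fb_arr < 0) | (fb_arr > 1)):
        raise ValueError("fraction bound must lie in [0, 1]")
    out = dmax * fb_arr
    return float(out) if out.ndim == 0 else out


def _fit_once(series: TitrationSeries, x0: np.ndarray, weights: np.ndarray):
    """Single least-squares run of the shared-K_D model.

    ``weights`` is a per-residue column of residual weights; the ligand-free
    reference column (residual identically zero by construction) is excluded
    from the residual vector so it does not distort the error estimate.
    """
    lt = series.ligand_totals
    pt = series.protein_total
    Y = series.csp  # (R, T)
    R = Y.shape[0]

    def residuals(theta):
        kd = theta[0]
        dmax = theta[1:]
        fb = fraction_bound(pt, lt, kd)
        resid = (dmax[:, None] * fb[None, :] - Y) * weights
        return resid[:, 1:].ravel()

    lb = np.concatenate([[1e-9], np.full(R, -np.inf)])
    ub = np.concatenate([[KD_UPPER], np.full(R, np.inf)])
    return least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)


def fit_kd(
    series: TitrationSeries,
    mode: Literal["per_residue", "global_shared_kd"] = "global_shared_kd",
) -> BindingFit | dict[int, BindingFit]:
    """Nonlinear least-squares fit of (K_D, ddelta_max) to a titration.

    ``global_shared_kd`` shares one K_D across residues with residue-specific
    ddelta_max; ``per_residue`` returns an independent fit per residue keyed
    by residue number. Standard errors come from the covariance at the
    optimum; non-identifiable fits (K_D pinned at the bound or a singular
    normal matrix) are flagged ``converged=False`` rather than silently
    returned as estimates.
    """
    if series.n_points < 4:
        raise ValueError("need at least 4 titration points")
    if np.allclose(series.csp, 0.0):
        raise ValueError("no perturbation: all CSPs are zero")

    if mode == "per_residue":
        out: dict[int, BindingFit] = {}
        for i, resnum in enumerate(series.residues):
            sub = TitrationSeries(
                protein_total=series.protein_total,
                ligand_totals=series.ligand_totals,
                csp=series.csp[i : i + 1],
                residues=[resnum],
            )
            out[resnum] = fit_kd(sub, mode="global_shared_kd")
        return out
    if mode != "global_shared_kd":
        raise ValueError(f"unknown mode {mode!r}")

    # stage 1: unweighted multi-start over K_D
    R = series.csp.shape[0]
    uniform = np.ones((R, 1))
    best = None
    for kd0 in KD_STARTS:
        fb0 = fraction_bound(series.protein_total, series.ligand_totals[-1], kd0)
        x0 = np.concatenate([[kd0], series.csp[:, -1] / max(fb0, 1e-6)])
        res = _fit_once(series, x0, uniform)
        if best is None or res.cost < best.cost:
            best = res

    # stage 2: weighted refit. CSP noise scales with the perturbation
    # amplitude, so residuals are weighted by 1/|dmax| (clamped to avoid
    # blowing up unperturbed residues) with one pooled error scale.
    amp = np.abs(best.x[1:])
    w = (1.0 / np.maximum(amp, 0.1 * max(amp.max(), 1e-9)))[:, None]
    best = _fit_once(series, best.x, w)

    kd = float(best.x[0])
    dmax = best.x[1:]
    fb_fit = fraction_bound(series.protein_total, series.ligand_totals, kd)
    rss = float(((dmax[:, None] * fb_fit[None, :] - series.csp) ** 2).sum())
    n_obs = series.csp[:, 1:].size
    n_par = len(best.x)

    converged = bool(best.success)
    se_kd = np.nan
    se_dmax = np.full(len(dmax), np.nan)
    # Non-identifiability checks. K_D is identified only by the *curvature*
    # of the binding isotherm over the sampled ligand range: if a straight
    # line through the origin explains the data as well as the isotherm, or
    # the fitted K_D sits far beyond the sampled range (fb never leaves the
    # linear regime), the fit is flagged rather than reported.
    lt = series.ligand_totals
    Y = series.csp
    denom = float((lt * lt).sum())
    slopes = (Y * lt[None, :]).sum(axis=1) / denom
    rss_linear = float(((slopes[:, None] * lt[None, :] - Y) ** 2).sum())
    if rss_linear <= rss * (1.0 + 1e-3) + 1e-15:
        converged = False
    if kd > 0.99 * KD_UPPER or kd > 25.0 * float(lt[-1]):
        converged = False
    if not converged:
        pass
    else:
        J = best.jac
        JTJ = J.T @ J
        try:
            cond = np.linalg.cond(JTJ)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            converged = False
        else:
            dof = max(n_obs - n_par, 1)
            # pooled error scale from the *weighted* residuals, consistent
            # with the weighted jacobian
            s2 = 2.0 * best.cost / dof
            cov = np.linalg.inv(JTJ) * s2
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se_kd = float(se[0])
            se_dmax = se[1:]

    return BindingFit(
        kd=max(kd, 1e-12),
        dmax=dmax,
        se_kd=se_kd if converged else np.nan,
        se_dmax=se_dmax if converged else np.full(len(dmax), np.nan),
        rss=rss,
        converged=converged,
        residues=list(series.residues),
    )


def csp_profile_compare(
    a: Mapping[int, float], b: Mapping[int, float]
) -> dict:
    """Compare two per-residue CSP profiles on their residue overlap.

    Returns the aligned difference (a - b), the Spearman rank correlation
    over the overlap, and the residues present in only one profile.
    """
    common = sorted(set(a) & set(b))
    if len(common) < 3:
        raise ValueError(f"profiles overlap in only {len(common)} residues; need >= 3")
    va = np.array([a[r] for r in common], dtype=float)
    vb = np.array([b[r] for r in common], dtype=float)
    rho, pvalue = spearmanr(va, vb)
    return {
        "residues": common,
        "difference": va - vb,
        "spearman_rho": float(rho),
        "pvalue": float(pvalue),
        "only_in_a": sorted(set(a) - set(b)),
        "only_in_b": sorted(set(b) - set(a)),
    }
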