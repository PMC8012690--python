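"""Michaelis–Menten kinetics per NAT2 allele and drug.

Velocity-vs-concentration data for each allele x drug x replicate are fit
to v = Vmax.[S]/(Km + [S]), either through the classical Lineweaver-Burk
double-reciprocal regression (the estimator used to produce the reference
tables this package reproduces) or by nonlinear least squares.  Intrinsic
clearance CLint = Vmax/Km summarizes metabolic efficiency; relative
clearance expresses it as a percentage of the *4 reference, and Tukey HSD
compares alleles with the a/b/c significance-letter convention
(a: p<0.05 vs *4, b: vs *5, c: vs *6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, NonConvergentFitError
from .star_allele import allele_sort_key

logger = logging.getLogger(__name__)

#: the eight substrate drugs, in reporting order
DRUGS = ("AGT", "DDP", "HLZ", "INH", "PZ", "PA", "SMZ", "SP")

#: Tukey significance letters: which allele each letter marks a difference from
LETTER_REFERENCES = (("a", "*4"), ("b", "*5"), ("c", "*6"))


@dataclass(frozen=True)
class ReactionObservation:
    """One measured velocity: drug, allele, replicate, [S] (uM), v."""

    drug: str
    allele: str
    replicate: int
    substrate_conc: float
    velocity: float

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if self.substrate_conc < 0:
            raise ValueError("substrate_conc must be >= 0")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters for one replicate."""

    km: float
    vmax: float
    method: str
    n_points: int

    @property
    def clint(self) -> float:
        return self.vmax / self.km


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- SE across replicates."""

    mean: float
    se: float
    n: int
    values: tuple = ()


def mean_se(values: Sequence[float]) -> SummaryStat:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return SummaryStat(float(arr.mean()), se, int(arr.size), tuple(arr))


def _extract_sv(observations, velocity):
    if velocity is not None:
        s = np.asarray(observations, dtype=float)
        v = np.asarray(velocity, dtype=float)
    else:
        s = np.array([o.substrate_conc for o in observations], dtype=float)
        v = np.array([o.velocity for o in observations], dtype=float)
    if s.shape != v.shape:
        raise ValueError("concentration and velocity arrays differ in length")
    return s, v


def fit_michaelis_menten(
    observations: Sequence[ReactionObservation] | Sequence[float],
    velocity: Sequence[float] | None = None,
    method: str = "lineweaver_burk",
    signal_floor: float = 0.0,
) -> MMFit:
    """Fit Km and Vmax for one drug x allele x replicate curve.

    ``lineweaver_burk`` regresses 1/v on 1/[S] by ordinary least squares
    over points with [S] > 0 and v > 0, giving Vmax = 1/intercept and
    Km = slope/intercept.  ``nls`` fits the Michaelis-Menten equation
    directly (trust-region least squares with positivity bounds),
    initialized from the Lineweaver-Burk estimate where that estimate is
    physical and from the data otherwise.

    [S] = 0 rows are blank checks, never regression points.  Velocities at
    or below ``signal_floor`` are dropped with a warning (detection-limit
    handling); at least 3 distinct positive concentrations must remain.
    """
    if method not in ("lineweaver_burk", "nls"):
        raise ValueError(f"unknown method {method!r}")
    s, v = _extract_sv(observations, velocity)

    blanks = v[s == 0]
    if blanks.size and np.any(blanks > max(signal_floor, 0.0)):
        logger.warning("nonzero velocity at [S]=0 (max %.3g); blank rows are "
                       "ignored in the fit", blanks.max())
    mask = (s > 0) & (v > max(signal_floor, 0.0))
    if signal_floor > 0:
        n_floor = int(((s > 0) & (v > 0) & (v <= signal_floor)).sum())
        if n_floor:
            logger.warning("dropped %d observation(s) at or below the signal "
                           "floor %.3g", n_floor, signal_floor)
    s, v = s[mask], v[mask]
    if np.unique(s).size < 3:
        raise InsufficientDataError(
            f"need >=3 distinct positive concentrations, got {np.unique(s).size}")

    km_lb, vmax_lb, err = _lineweaver_burk(s, v)
    if method == "lineweaver_burk":
        if err is not None:
            raise NonConvergentFitError(err)
        return MMFit(km_lb, vmax_lb, method, int(s.size))

    if err is None and np.isfinite(km_lb) and km_lb > 0 and vmax_lb > 0:
        p0 = (vmax_lb, km_lb)
    else:  # data-driven fallback when the double-reciprocal line is unphysical
        vmax0 = 1.2 * float(v.max())
        km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
        p0 = (vmax0, max(km0, 1e-9))
    try:
        popt, _ = optimize.curve_fit(
            lambda S, vm, km: vm * S / (km + S), s, v, p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise NonConvergentFitError(str(exc)) from exc
    return MMFit(float(popt[1]), float(popt[0]), method, int(s.size))


def _lineweaver_burk(s, v):
    """OLS of 1/v on 1/[S]; returns (km, vmax, error_message_or_None)."""
    slope, intercept = np.polyfit(1.0 / s, 1.0 / v, 1)
    if intercept <= 0:
        return math.nan, math.nan, (
            f"non-positive Lineweaver-Burk intercept ({intercept:.3g}); "
            "fit reported as non-convergent")
    if slope <= 0:
        return math.nan, math.nan, (
            f"non-positive Lineweaver-Burk slope ({slope:.3g}); "
            "fit reported as non-convergent")
    return float(slope / intercept), float(1.0 / intercept), None


def fit_dataset(reactions: pd.DataFrame, method: str = "lineweaver_burk",
                signal_floor: float = 0.0) -> pd.DataFrame:
    """Fit every (drug, allele, replicate) curve in a reaction table.

    Expects columns ``drug, allele, replicate, conc_um, velocity``; returns
    one row per curve with ``km``, ``vmax`` and ``clint``.
    """
    required = {"drug", "allele", "replicate", "conc_um", "velocity"}
    missing = required - set(reactions.columns)
    if missing:
        raise ValueError(f"reaction table missing column(s): {sorted(missing)}")
    rows = []
    for (drug, allele, rep), grp in reactions.groupby(
            ["drug", "allele", "replicate"], sort=True):
        fit = fit_michaelis_menten(
            grp["conc_um"].to_numpy(), grp["velocity"].to_numpy(),
            method=method, signal_floor=signal_floor)
        rows.append({"drug": drug, "allele": allele, "replicate": rep,
                     "km": fit.km, "vmax": fit.vmax, "clint": fit.clint})
    return pd.DataFrame(rows)


def compute_clint(params: Sequence[MMFit] | Sequence[tuple]) -> SummaryStat:
    """CLint = Vmax/Km per replicate, then mean +/- SE across replicates.

    Averaging the per-replicate ratios (rather than taking the ratio of
    mean Vmax to mean Km) is what the reference tables' internal arithmetic
    reflects.
    """
    if len(params) == 0:
        raise ValueError("zero replicates")
    ratios = [
        (p.clint if isinstance(p, MMFit) else p[1] / p[0]) for p in params
    ]
    return mean_se(ratios)


def relative_clearance(allele_clint: float, reference_clint: float) -> float:
    """CLint as a percentage of the *4 reference CLint."""
    if reference_clint <= 0:
        raise ValueError("reference CLint must be > 0")
    return 100.0 * allele_clint / reference_clint


@dataclass
class TukeyResult:
    """Pairwise Tukey-HSD p-values and significance letters per group."""

    groups: tuple
    p_values: dict  # frozenset({g1, g2}) -> adjusted p
    letters: dict  # group -> e.g. "a,b"
    degenerate: bool = False

    def p(self, g1: str, g2: str) -> float:
        return self.p_values[frozenset((g1, g2))]


def compare_alleles_tukey(groups: Mapping[str, Sequence[float]],
                          alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD over all allele pairs with Table-style letters.

    Letters mark p < ``alpha`` against the preceding alleles in the
    *4 < *5 < *6 order (a = differs from *4, b = from *5, c = from *6).
    Zero-variance inputs are reported as ``degenerate`` with p = 1 for
    equal means and p = 0 otherwise, instead of crashing on a zero mean
    square error.
    """
    names = sorted(groups, key=allele_sort_key)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs >=2 replicates, got {arr.size}")

    pooled_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    p_values: dict = {}
    degenerate = pooled_ss == 0.0
    if degenerate:
        logger.warning("zero within-group variance; Tukey p-values degenerate")
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                equal = math.isclose(arrays[i].mean(), arrays[j].mean(),
                                     rel_tol=0.0, abs_tol=0.0)
                p_values[frozenset((names[i], names[j]))] = 1.0 if equal else 0.0
    else:
        res = stats.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p_values[frozenset((names[i], names[j]))] = float(
                    res.pvalue[i, j])

    letters = {}
    for g in names:
        marks = [
            letter for letter, ref in LETTER_REFERENCES
            if ref in groups and ref != g
            and allele_sort_key(ref) < allele_sort_key(g)
            and p_values[frozenset((g, ref))] < alpha
        ]
        letters[g] = ",".join(marks)
    return TukeyResult(tuple(names), p_values, letters, degenerate)


def summarize_kinetics(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Reference-table-shaped summary: mean +/- SE of Km, Vmax, CLint.

    ``fits`` is the per-replicate output of :func:`fit_dataset`.  Adds
    Tukey significance letters per drug for each parameter when every
    allele has >=2 replicates.
    """
    rows = []
    for drug, dgrp in fits.groupby("drug", sort=False):
        letters = {}
        for param in ("km", "vmax", "clint"):
            groups = {a: g[param].to_numpy()
                      for a, g in dgrp.groupby("allele", sort=True)}
            if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
                letters[param] = compare_alleles_tukey(groups, alpha).letters
            else:
                letters[param] = {a: "" for a in groups}
        for allele, agrp in dgrp.groupby("allele", sort=True):
            row = {"drug": drug, "allele": allele, "n": len(agrp)}
            for param in ("km", "vmax", "clint"):
                ss = mean_se(agrp[param].to_numpy())
                row[f"{param}_mean"] = ss.mean
                row[f"{param}_se"] = ss.se
                row[f"{param}_letters"] = letters[param][allele]
            rows.append(row)
    out = pd.DataFrame(rows)
    out["__d"] = out["drug"].map({d: i for i, d in enumerate(DRUGS)})
    out = (out.sort_values(["__d", "allele"]).drop(columns="__d")
           .reset_index(drop=True))
    return out
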