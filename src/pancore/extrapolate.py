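"""Genome-sampling trajectories and pan-genome openness regression.

For S strains, every strain combination is enumerated exhaustively (no
Monte-Carlo): for each n in 1..S the core and pan curves collect one value
per size-n combination (C(S, n) values) and the new-gene curve one value
per (combination, last-added genome) ordering, S!/[(n-1)!(S-n)!] values.

Three regressions summarise the trajectories:

* core decay      F_c(n) = kappa_c * exp(-n / tau_c) + Omega   (fit to per-n means)
* new-gene decay  F_s(n) = kappa_s * exp(-n / tau_s) + tg_theta (fit to medians)
* Heaps' law      P_s(n) = kappa * n ** gamma                   (fit to medians)

Omega estimates the stable core-genome size, tg_theta the asymptotic number
of new genes per added genome, and the Heaps exponent classifies the
pan-genome: gamma < 0 closed, 0 < gamma < 1 open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .profile import MAX_STRAINS, PanProfile

FIT_XTOL = 1e-10


def combination_count(S: int, n: int) -> int:
    """Number of (combination, last-added genome) orderings at step n.

    Equals S! / [(n-1)! (S-n)!] = n * C(S, n): each size-n combination is
    reached via n choices of which genome was added last.
    """
    if not 1 <= n <= S:
        raise ValueError(f"n={n} outside 1..S={S}")
    return factorial(S) // (factorial(n - 1) * factorial(S - n))


@dataclass
class Trajectory:
    """Per-step value multisets of a genome-accumulation curve."""

    kind: str  # core | new | pan
    S: int
    values: dict[int, np.ndarray] = field(default_factory=dict)  # n -> multiset

    def mean(self) -> np.ndarray:
        return np.array([self.values[n].mean() for n in range(1, self.S + 1)])

    def median(self) -> np.ndarray:
        return np.array([np.median(self.values[n]) for n in range(1, self.S + 1)])

    def std(self) -> np.ndarray:
        return np.array([self.values[n].std(ddof=0) for n in range(1, self.S + 1)])

    def statistic(self, which: str) -> np.ndarray:
        if which == "mean":
            return self.mean()
        if which == "median":
            return self.median()
        raise ValueError(f"unknown statistic {which!r}")

    @property
    def steps(self) -> np.ndarray:
        return np.arange(1, self.S + 1)


def _guard(profile: PanProfile) -> None:
    if profile.n_strains > MAX_STRAINS:
        raise ValueError(
            f"exhaustive enumeration is limited to S <= {MAX_STRAINS}; "
            "subsample the strain set first"
        )


def core_trajectory(profile: PanProfile) -> Trajectory:
    """Clusters present in *all* members of every size-n strain subset."""
    _guard(profile)
    S = profile.n_strains
    m = profile.matrix
    traj = Trajectory(kind="core", S=S)
    for n in range(1, S + 1):
        vals = [
            int(m[:, list(sub)].all(axis=1).sum())
            for sub in combinations(range(S), n)
        ]
        traj.values[n] = np.array(vals, dtype=float)
    return traj


def pan_trajectory(profile: PanProfile) -> Trajectory:
    """Clusters present in *at least one* member of every size-n subset."""
    _guard(profile)
    S = profile.n_strains
    m = profile.matrix
    traj = Trajectory(kind="pan", S=S)
    for n in range(1, S + 1):
        vals = [
            int(m[:, list(sub)].any(axis=1).sum())
            for sub in combinations(range(S), n)
        ]
        traj.values[n] = np.array(vals, dtype=float)
    return traj


def new_gene_trajectory(profile: PanProfile) -> Trajectory:
    """Clusters contributed by the genome added at step n.

    For each (size-(n-1) subset, added genome g not in the subset): clusters
    present in g and absent from every subset member.  At n = 1 the value is
    the genome's own cluster total.
    """
    _guard(profile)
    S = profile.n_strains
    m = profile.matrix
    traj = Trajectory(kind="new", S=S)
    for n in range(1, S + 1):
        vals = []
        for sub in combinations(range(S), n - 1):
            absent = (
                ~m[:, list(sub)].any(axis=1) if sub else np.ones(m.shape[0], dtype=bool)
            )
            for g in range(S):
                if g in sub:
                    continue
                vals.append(int((m[:, g] & absent).sum()))
        traj.values[n] = np.array(vals, dtype=float)
        assert len(vals) == combination_count(S, n)
    return traj


@dataclass
class HeapsFit:
    kappa: float
    gamma: float
    rss: float
    stderr: dict[str, float]

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.kappa * np.asarray(n, dtype=float) ** self.gamma


@dataclass
class CoreDecayFit:
    kappa_c: float
    tau_c: float
    omega: float
    rss: float
    stderr: dict[str, float]
    unidentifiable: bool = False

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.kappa_c * np.exp(-np.asarray(n, dtype=float) / self.tau_c) + self.omega


@dataclass
class NewGeneFit:
    kappa_s: float
    tau_s: float
    tg_theta: float
    rss: float
    stderr: dict[str, float]
    unidentifiable: bool = False

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.kappa_s * np.exp(-np.asarray(n, dtype=float) / self.tau_s) + self.tg_theta


def _exp_decay(n, kappa, tau, asymptote):
    return kappa * np.exp(-n / tau) + asymptote


def _fit_exp_decay(n: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Damped least squares for kappa*exp(-n/tau) + c; returns (params, SEs, flat?)."""
    if len(n) < 3:
        raise ValueError("exponential decay fit needs at least 3 points")
    if np.allclose(y, y[0]):
        params = np.array([0.0, 1.0, y[0]])
        return params, np.full(3, np.nan), True
    if np.allclose(y[1:], y[-1]):
        # step at n=1, flat afterwards: any sufficiently small tau fits
        # exactly, so tau is unidentifiable
        params = np.array([y[0] - y[-1], 1e-9, y[-1]])
        return params, np.full(3, np.nan), True
    p0 = [y[0] - y[-1], 1.0, y[-1]]
    params, cov = curve_fit(
        _exp_decay, n.astype(float), y.astype(float), p0=p0, maxfev=20000,
        xtol=FIT_XTOL, ftol=FIT_XTOL,
    )
    se = np.sqrt(np.diag(cov)) if np.all(np.isfinite(cov)) else np.full(3, np.nan)
    return params, se, False


def fit_core_decay(trajectory: Trajectory, statistic: str = "mean") -> CoreDecayFit:
    """Fit the core-genome decay; Omega is the predicted stable core size."""
    n = trajectory.steps.astype(float)
    y = trajectory.statistic(statistic)
    params, se, flat = _fit_exp_decay(n, y)
    rss = float(((y - _exp_decay(n, *params)) ** 2).sum())
    return CoreDecayFit(
        kappa_c=float(params[0]), tau_c=float(params[1]), omega=float(params[2]),
        rss=rss,
        stderr={"kappa_c": float(se[0]), "tau_c": float(se[1]), "omega": float(se[2])},
        unidentifiable=flat,
    )


def fit_new_gene_decay(trajectory: Trajectory, statistic: str = "median") -> NewGeneFit:
    """Fit the new-gene decay; tg_theta > 0 is open-pan-genome evidence."""
    n = trajectory.steps.astype(float)
    y = trajectory.statistic(statistic)
    params, se, flat = _fit_exp_decay(n, y)
    rss = float(((y - _exp_decay(n, *params)) ** 2).sum())
    return NewGeneFit(
        kappa_s=float(params[0]), tau_s=float(params[1]), tg_theta=float(params[2]),
        rss=rss,
        stderr={"kappa_s": float(se[0]), "tau_s": float(se[1]), "tg_theta": float(se[2])},
        unidentifiable=flat,
    )


def _power_law(n, kappa, gamma):
    return kappa * n ** gamma


def fit_heaps(trajectory: Trajectory, statistic: str = "median") -> HeapsFit:
    """Fit Heaps' law P_s = kappa * n**gamma to the pan-genome curve.

    Initialised from the ordinary log-log linear regression, then refined
    by nonlinear least squares on the original scale.
    """
    n = trajectory.steps.astype(float)
    y = trajectory.statistic(statistic)
    if np.any(y <= 0):
        raise ValueError("Heaps fit requires strictly positive pan-genome sizes")
    if np.allclose(y, y[0]):
        return HeapsFit(
            kappa=float(y[0]), gamma=0.0, rss=0.0,
            stderr={"kappa": float("nan"), "gamma": float("nan")},
        )
    lr = linregress(np.log(n), np.log(y))
    p0 = [float(np.exp(lr.intercept)), float(lr.slope)]
    params, cov = curve_fit(
        _power_law, n, y.astype(float), p0=p0, maxfev=20000,
        xtol=FIT_XTOL, ftol=FIT_XTOL,
    )
    se = np.sqrt(np.diag(cov)) if np.all(np.isfinite(cov)) else np.full(2, np.nan)
    rss = float(((y - _power_law(n, *params)) ** 2).sum())
    return HeapsFit(
        kappa=float(params[0]), gamma=float(params[1]), rss=rss,
        stderr={"kappa": float(se[0]), "gamma": float(se[1])},
    )


def classify_openness(gamma: float) -> str:
    """Openness label from the Heaps exponent.

    gamma < 0: pan-genome size approaches a constant -> closed.
    0 < gamma < 1: size grows unboundedly but sublinearly -> open.
    gamma == 0 or gamma >= 1: outside the model's informative range.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if gamma < 0:
        return "closed"
    if 0 < gamma < 1:
        return "open"
    return "indeterminate"


def leave_one_out_spread(profile: PanProfile) -> dict[str, float]:
    """Dispersion of Omega, tg_theta and gamma across leave-one-strain-out refits.

    The study-level +/- spreads are computed here as the standard deviation
    of each fitted asymptote over the S profiles obtained by dropping one
    strain at a time — an explicit construction of this package, reported
    as such.  Requires S >= 4 so each refit keeps >= 3 points.
    """
    S = profile.n_strains
    if S < 4:
        raise ValueError("leave-one-out spread needs at least 4 strains")
    omegas, tgs, gammas = [], [], []
    for drop in range(S):
        keep = [j for j in range(S) if j != drop]
        sub_matrix = profile.matrix[:, keep]
        present = sub_matrix.any(axis=1)
        sub = PanProfile(
            strains=[profile.strains[j] for j in keep],
            matrix=sub_matrix[present],
            cluster_ids=[c for c, p in zip(profile.cluster_ids, present) if p],
        )
        omegas.append(fit_core_decay(core_trajectory(sub)).omega)
        tgs.append(fit_new_gene_decay(new_gene_trajectory(sub)).tg_theta)
        gammas.append(fit_heaps(pan_trajectory(sub)).gamma)
    return {
        "omega_sd": float(np.std(omegas, ddof=1)),
        "tg_theta_sd": float(np.std(tgs, ddof=1)),
        "gamma_sd": float(np.std(gammas, ddof=1)),
    }
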