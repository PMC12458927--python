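"""Two-state relaxation-to-equilibrium model for sorted-population trajectories.

A cell population is modeled as a mixture of transcriptionally Active and
Inactive cells that interconvert with first-order rates ``kon`` (Inactive ->
Active) and ``koff`` (Active -> Inactive), both in day^-1.  The active
fraction A(t) obeys

    dA/dt = kon (1 - A) - koff A = kon - (kon + koff) A

whose solution from initial condition A(t0) = A0 is the exponential
relaxation

    A(t) = A_eq + (A0 - A_eq) exp(-lambda (t - t0)),

with relaxation rate ``lambda = kon + koff`` and equilibrium active fraction
``A_eq = kon / (kon + koff)``.

Sorting a population by expression level prepares subpopulations displaced
from equilibrium (an expression-high sort starts with A0 > A_eq, an
expression-low sort with A0 < A_eq); both relax back to the same A_eq with
the same rate lambda, so jointly fitting the sorted trajectories identifies
(lambda, A_eq) and hence the switching rates kon and koff.

:class:`RelaxationModel` is the scikit-learn-style estimator performing the
joint nonlinear least-squares fit; :func:`fit_joint` and
:func:`bootstrap_ci` are thin functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "a_eq",
    "relax",
    "mean_residence_time",
    "time_to_equilibrium",
    "RelaxationModel",
    "TwoStateFit",
    "fit_joint",
    "bootstrap_ci",
]

_TRAJECTORY_COLUMNS = ("population", "day", "fraction_transcribing")


def a_eq(kon: float, koff: float) -> float:
    """Equilibrium active fraction kon / (kon + koff).

    Parameters are first-order switching rates in day^-1 (any common unit
    works; the result is dimensionless).
    """
    if not (np.isfinite(kon) and np.isfinite(koff)):
        raise ValueError("kon and koff must be finite")
    if kon < 0 or koff < 0:
        raise ValueError("kon and koff must be non-negative")
    total = kon + koff
    if total == 0:
        raise ValueError("kon + koff must be positive")
    return kon / total


def relax(t, t0: float, a0: float, a_eq: float, lam: float):
    """Active fraction at time ``t`` of the exponential relaxation.

    A(t) = a_eq + (a0 - a_eq) * exp(-lam * (t - t0)).

    ``t`` may be a scalar or array of days; ``t >= t0`` is required.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < t0):
        raise ValueError(f"t must be >= t0 ({t0})")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not (0.0 <= a0 <= 1.0 and 0.0 <= a_eq <= 1.0):
        raise ValueError("a0 and a_eq must lie in [0, 1]")
    out = a_eq + (a0 - a_eq) * np.exp(-lam * (t - t0))
    return float(out) if out.ndim == 0 else out


def mean_residence_time(k: float) -> float:
    """Mean waiting time 1/k (days) before leaving a state with exit rate k (day^-1)."""
    if not np.isfinite(k) or k <= 0:
        raise ValueError("rate must be positive and finite")
    return 1.0 / k


def time_to_equilibrium(a0: float, a_eq: float, lam: float, tol: float) -> float:
    """Days after t0 until |A(t) - a_eq| first drops to ``tol``.

    Closed form ln(|a0 - a_eq| / tol) / lam, floored at zero (already within
    tolerance at t0).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    gap = abs(a0 - a_eq)
    if gap <= tol:
        return 0.0
    return math.log(gap / tol) / lam


@dataclass
class TwoStateFit:
    """Result of a joint two-state relaxation fit.

    Rates are day^-1.  ``a0_by_population`` maps population label to its
    fitted initial active fraction.  ``ci`` (filled by bootstrap) maps
    parameter name to a (lo, hi) 95% percentile interval.
    """

    kon: float
    koff: float
    lam: float
    a_eq: float
    a0_by_population: dict
    rss: float
    mode: str
    t0: float = 0.0
    n_obs: int = 0
    converged: bool = True
    n_starts: int = 1
    ci: dict = field(default_factory=dict)

    def predict(self, population: str, t) -> np.ndarray:
        return relax(t, self.t0, self.a0_by_population[population], self.a_eq, self.lam)

    def to_dict(self) -> dict:
        return {
            "kon": self.kon,
            "koff": self.koff,
            "lambda": self.lam,
            "a_eq": self.a_eq,
            "a0_by_population": dict(self.a0_by_population),
            "rss": self.rss,
            "mode": self.mode,
            "t0": self.t0,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def _check_trajectories(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    frac = df["fraction_transcribing"].to_numpy(dtype=float)
    if np.any(~np.isfinite(frac)) or np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("fraction_transcribing must be finite and in [0, 1]")
    for pop, sub in df.groupby("population"):
        if sub["day"].nunique() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 distinct days")
    return df


class RelaxationModel(BaseEstimator):
    """Joint two-state relaxation fit across sorted populations.

    Minimizes the summed squared residuals of A(t) = A_eq + (A0_p - A_eq)
    e^{-lambda (t - t0)} over all observations of all populations, sharing
    lambda and A_eq across populations while each population p keeps its own
    initial fraction A0_p.  kon and koff follow from kon = A_eq * lambda and
    koff = lambda - kon.

    Parameters
    ----------
    mode : {"fitted_equilibrium", "fixed_equilibrium"}
        Whether the equilibrium fraction is a free parameter or pinned at
        ``a_eq_fixed``.
    a_eq_fixed : float
        Equilibrium fraction used in ``fixed_equilibrium`` mode (default
        0.20, a typical bulk steady-state transcribing fraction).
    t0 : float
        Sorting time in days; observations are taken at days >= t0.
    n_starts : int
        Multi-start count for the optimizer.  Initial lambda values are
        drawn log-uniform on (0.01, 2) day^-1; initial fractions start from
        the data (earliest-day mean per population, last-day mean for A_eq).
    weighted : bool
        If True, weight residuals by sqrt(n_cells) (inverse binomial
        standard-deviation scaling).  Off by default: plain least squares on
        fractions.
    lam_bounds : tuple
        Box constraint for lambda (day^-1).
    random_state : int or None
        Seeds the multi-start draws; the fit is reproducible for a fixed
        seed.

    Attributes (after ``fit``)
    --------------------------
    kon_, koff_, lambda_, a_eq_ : float
        Fitted rates (day^-1) and equilibrium fraction; always satisfy
        lambda_ = kon_ + koff_ and a_eq_ = kon_ / lambda_ exactly.
    a0_by_population_ : dict
        Fitted initial active fraction per population.
    rss_ : float
        Residual sum of squares at the optimum.
    result_ : TwoStateFit
        Full structured result.
    """

    def __init__(
        self,
        mode: str = "fitted_equilibrium",
        a_eq_fixed: float = 0.20,
        t0: float = 0.0,
        n_starts: int = 20,
        weighted: bool = False,
        lam_bounds: tuple = (1e-4, 10.0),
        random_state: int | None = 0,
    ):
        self.mode = mode
        self.a_eq_fixed = a_eq_fixed
        self.t0 = t0
        self.n_starts = n_starts
        self.weighted = weighted
        self.lam_bounds = lam_bounds
        self.random_state = random_state

    # -- internal ---------------------------------------------------------

    def _pack(self, lam, aeq, a0s, fit_aeq):
        return np.concatenate(([lam, aeq] if fit_aeq else [lam], a0s))

    def _residual_fn(self, days, fracs, pop_idx, n_pop, fit_aeq, weights):
        t0 = self.t0
        aeq_fixed = self.a_eq_fixed

        def resid(theta):
            lam = theta[0]
            if fit_aeq:
                aeq = theta[1]
                a0s = theta[2:]
            else:
                aeq = aeq_fixed
                a0s = theta[1:]
            pred = aeq + (a0s[pop_idx] - aeq) * np.exp(-lam * (days - t0))
            r = fracs - pred
            return r * weights if weights is not None else r

        return resid

    def fit(self, trajectories: pd.DataFrame, y=None, x0: np.ndarray | None = None):
        """Fit the model to a trajectory table.

        ``trajectories`` needs columns population, day,
        fraction_transcribing and optionally n_cells (used only when
        ``weighted``) and replicate.
        """
        if self.mode not in ("fitted_equilibrium", "fixed_equilibrium"):
            raise ValueError(f"unknown mode {self.mode!r}")
        df = _check_trajectories(pd.DataFrame(trajectories))
        if df["population"].nunique() < 2:
            raise ValueError("joint fit needs at least 2 populations")
        if np.any(df["day"].to_numpy(dtype=float) < self.t0):
            raise ValueError("observations before t0")

        pops = sorted(df["population"].unique())
        pop_to_idx = {p: i for i, p in enumerate(pops)}
        days = df["day"].to_numpy(dtype=float)
        fracs = df["fraction_transcribing"].to_numpy(dtype=float)
        pop_idx = df["population"].map(pop_to_idx).to_numpy()
        fit_aeq = self.mode == "fitted_equilibrium"

        if np.allclose(fracs, fracs[0]):
            raise ValueError(
                "all observations share one value; lambda is unidentifiable"
            )
        n_free = 1 + (1 if fit_aeq else 0) + len(pops)
        if len(df) < n_free:
            raise ValueError(
                f"{len(df)} observations cannot identify {n_free} parameters"
            )

        weights = None
        if self.weighted:
            if "n_cells" not in df.columns:
                raise ValueError("weighted fit requires an n_cells column")
            weights = np.sqrt(df["n_cells"].to_numpy(dtype=float))

        resid = self._residual_fn(days, fracs, pop_idx, len(pops), fit_aeq, weights)

        # data-driven starting fractions
        by_pop_first = df.loc[df.groupby("population")["day"].transform("min") == df["day"]]
        a0_start = (
            by_pop_first.groupby("population")["fraction_transcribing"].mean().loc[pops].to_numpy()
        )
        last_day = df["day"].max()
        aeq_start = float(df.loc[df["day"] == last_day, "fraction_transcribing"].mean())
        aeq_start = min(max(aeq_start, 1e-3), 1 - 1e-3)

        lo = np.concatenate(([self.lam_bounds[0]], [0.0] * (n_free - 1)))
        hi = np.concatenate(([self.lam_bounds[1]], [1.0] * (n_free - 1)))

        rng = np.random.default_rng(self.random_state)
        starts = []
        if x0 is not None:
            starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))
        lam_draws = np.exp(rng.uniform(np.log(0.01), np.log(2.0), size=self.n_starts))
        for lam0 in lam_draws:
            starts.append(self._pack(lam0, aeq_start, a0_start, fit_aeq))

        best = None
        for s in starts:
            sol = least_squares(resid, s, bounds=(lo, hi), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol

        theta = best.x
        lam = float(theta[0])
        aeq = float(theta[1]) if fit_aeq else float(self.a_eq_fixed)
        a0s = theta[2:] if fit_aeq else theta[1:]
        kon = aeq * lam
        koff = lam - kon

        self.lambda_ = lam
        self.a_eq_ = aeq
        self.kon_ = kon
        self.koff_ = koff
        self.a0_by_population_ = {p: float(a0s[i]) for p, i in pop_to_idx.items()}
        self.rss_ = float(2.0 * best.cost)
        self.result_ = TwoStateFit(
            kon=kon,
            koff=koff,
            lam=lam,
            a_eq=aeq,
            a0_by_population=self.a0_by_population_,
            rss=self.rss_,
            mode=self.mode,
            t0=self.t0,
            n_obs=len(df),
            converged=bool(best.success),
            n_starts=len(starts),
        )
        return self

    def predict(self, trajectories: pd.DataFrame) -> np.ndarray:
        """Predicted active fraction for each (population, day) row."""
        if not hasattr(self, "result_"):
            raise ValueError("model is not fitted")
        df = pd.DataFrame(trajectories)
        return np.array(
            [
                self.result_.predict(p, t)
                for p, t in zip(df["population"], df["day"].astype(float))
            ]
        )

    def predicted_curve(self, t_max: float, n: int = 200) -> pd.DataFrame:
        """Dense model curves for each population from t0 to t_max days."""
        if not hasattr(self, "result_"):
            raise ValueError("model is not fitted")
        ts = np.linspace(self.t0, t_max, n)
        rows = []
        for pop in self.result_.a0_by_population:
            rows.append(
                pd.DataFrame(
                    {"population": pop, "day": ts, "fraction_transcribing": self.result_.predict(pop, ts)}
                )
            )
        return pd.concat(rows, ignore_index=True)


def fit_joint(
    trajectories: pd.DataFrame,
    mode: str = "fitted_equilibrium",
    a_eq_fixed: float = 0.20,
    t0: float = 0.0,
    n_starts: int = 20,
    weighted: bool = False,
    random_state: int | None = 0,
) -> TwoStateFit:
    """Jointly fit the relaxation model; see :class:`RelaxationModel`."""
    model = RelaxationModel(
        mode=mode,
        a_eq_fixed=a_eq_fixed,
        t0=t0,
        n_starts=n_starts,
        weighted=weighted,
        random_state=random_state,
    )
    return model.fit(trajectories).result_


def bootstrap_ci(
    trajectories: pd.DataFrame,
    mode: str = "fitted_equilibrium",
    n_boot: int = 1000,
    seed: int | None = 0,
    a_eq_fixed: float = 0.20,
    t0: float = 0.0,
    n_starts: int = 20,
    resample: str = "replicate",
    alpha: float = 0.05,
) -> dict:
    """Percentile bootstrap confidence intervals for the joint fit.

    Resampling unit is the replicate measurement within each (population,
    day) cell (``resample="replicate"``); with ``resample="trajectory"``
    whole per-replicate trajectories are resampled instead, redrawing (up to
    100 times) any resample leaving a population with fewer than 2 distinct
    days.  Refits warm-start from the full-data optimum.  Returns a dict
    with the point fit and ``(lo, hi)`` percentile intervals per parameter.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if resample not in ("replicate", "trajectory"):
        raise ValueError(f"unknown resample scheme {resample!r}")
    df = _check_trajectories(pd.DataFrame(trajectories)).reset_index(drop=True)
    rng = np.random.default_rng(seed)

    model = RelaxationModel(
        mode=mode, a_eq_fixed=a_eq_fixed, t0=t0, n_starts=n_starts, random_state=int(rng.integers(2**31))
    )
    point = model.fit(df).result_
    fit_aeq = mode == "fitted_equilibrium"
    pops = sorted(df["population"].unique())
    x_hat = np.concatenate(
        (
            [point.lam, point.a_eq] if fit_aeq else [point.lam],
            [point.a0_by_population[p] for p in pops],
        )
    )

    # fast array-level refit machinery: resamples only permute which rows are
    # drawn within each (population, day) cell, so days/pop indices are fixed
    days_all = df["day"].to_numpy(dtype=float)
    fracs_all = df["fraction_transcribing"].to_numpy(dtype=float)
    pop_idx_all = df["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()
    n_free = 1 + (1 if fit_aeq else 0) + len(pops)
    lo = np.concatenate(([1e-4], [0.0] * (n_free - 1)))
    hi = np.concatenate(([10.0], [1.0] * (n_free - 1)))
    x_hat = np.clip(x_hat, lo, hi)

    def refit(rows: np.ndarray) -> tuple:
        days, fracs, pidx = days_all[rows], fracs_all[rows], pop_idx_all[rows]

        def resid(theta):
            lam = theta[0]
            aeq = theta[1] if fit_aeq else a_eq_fixed
            a0s = theta[2:] if fit_aeq else theta[1:]
            return fracs - (aeq + (a0s[pidx] - aeq) * np.exp(-lam * (days - t0)))

        sol = least_squares(resid, x_hat, bounds=(lo, hi), method="trf")
        theta = sol.x
        lam = float(theta[0])
        aeq = float(theta[1]) if fit_aeq else float(a_eq_fixed)
        a0s = theta[2:] if fit_aeq else theta[1:]
        return lam, aeq, a0s

    cell_indices = {key: sub.index.to_numpy() for key, sub in df.groupby(["population", "day"])}
    if resample == "trajectory":
        if "replicate" not in df.columns:
            raise ValueError("trajectory resampling requires a replicate column")
        traj_indices = {key: sub.index.to_numpy() for key, sub in df.groupby(["population", "replicate"])}
        traj_keys = list(traj_indices)

    names = (["lambda", "a_eq", "kon", "koff"] if fit_aeq else ["lambda", "kon", "koff"]) + [
        f"a0_{p}" for p in pops
    ]
    draws = {n: np.empty(n_boot) for n in names}

    cell_arrays = list(cell_indices.values())
    for b in range(n_boot):
        if resample == "replicate":
            take = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in cell_arrays]
            )
        else:
            for _ in range(100):
                chosen = rng.choice(len(traj_keys), size=len(traj_keys), replace=True)
                take = np.concatenate([traj_indices[traj_keys[c]] for c in chosen])
                sample = df.loc[take]
                if all(sample[sample["population"] == p]["day"].nunique() >= 2 for p in pops):
                    break
            else:
                raise RuntimeError("could not draw a valid trajectory resample in 100 tries")
        lam, aeq, a0s = refit(take)
        draws["lambda"][b] = lam
        if fit_aeq:
            draws["a_eq"][b] = aeq
        draws["kon"][b] = aeq * lam
        draws["koff"][b] = lam - aeq * lam
        for i, p in enumerate(pops):
            draws[f"a0_{p}"][b] = a0s[i]

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci = {n: (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q))) for n, v in draws.items()}
    point.ci = ci
    return {"fit": point, "ci": ci, "n_boot": n_boot, "resample": resample}
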