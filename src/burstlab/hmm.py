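"""Two-state HMM segmentation of live-cell transcription traces and dwell-time kinetics.

Transcription-site intensity traces (one per allele, typically one frame
every 100 s for 512 frames) are segmented into active/inactive states with
a two-state Gaussian-emission hidden Markov model fit by Baum-Welch, pooled
across all traces of a population so that emission parameters are stable.
Viterbi decoding yields hard state paths, from which maximal constant-state
runs become dwell times; runs touching either trace boundary are censored
(their true length is unknown) and excluded from dwell medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.base import BaseEstimator

__all__ = [
    "BurstHMM",
    "fit_hmm",
    "decode",
    "extract_dwells",
    "dwell_cdf",
    "DwellSummary",
    "StateSequence",
    "traces_to_arrays",
]


@dataclass
class StateSequence:
    """Viterbi path and per-frame posterior probability of the active state."""

    states: np.ndarray  # 1 = active (higher emission mean), 0 = inactive
    posterior_active: np.ndarray
    allele_id: object = None


@dataclass
class DwellSummary:
    """Dwell durations in minutes, split by state, boundary runs excluded.

    ``n_censored_excluded`` counts runs touching a trace boundary; medians
    are over uncensored dwells only (censored runs would bias long dwells
    downward).
    """

    active_dwells: np.ndarray
    inactive_dwells: np.ndarray
    n_censored_excluded: int
    dt: float  # s

    @property
    def median_active(self) -> float:
        return float(np.median(self.active_dwells)) if len(self.active_dwells) else np.nan

    @property
    def median_inactive(self) -> float:
        return float(np.median(self.inactive_dwells)) if len(self.inactive_dwells) else np.nan

    def to_dict(self) -> dict:
        return {
            "median_active_min": self.median_active,
            "median_inactive_min": self.median_inactive,
            "n_active_dwells": int(len(self.active_dwells)),
            "n_inactive_dwells": int(len(self.inactive_dwells)),
            "n_censored_excluded": self.n_censored_excluded,
            "dt_s": self.dt,
        }


def traces_to_arrays(traces: pd.DataFrame) -> tuple[list, list[np.ndarray]]:
    """Split a long-format trace table into per-allele intensity arrays.

    Requires columns allele_id, frame, intensity; frames must be contiguous
    from 0 within each allele.
    """
    for col in ("allele_id", "frame", "intensity"):
        if col not in traces.columns:
            raise ValueError(f"trace table lacks column {col!r}")
    ids, arrays = [], []
    for aid, sub in traces.groupby("allele_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise ValueError(f"allele {aid!r}: frames are not contiguous from 0")
        vals = sub["intensity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"allele {aid!r}: non-finite intensities")
        ids.append(aid)
        arrays.append(vals)
    return ids, arrays


class BurstHMM(BaseEstimator):
    """Two-state Gaussian HMM for transcription traces (scikit-learn style).

    Fitting pools all traces (Baum-Welch over concatenated sequences);
    convergence when the log-likelihood improves by less than ``tol`` or
    after ``n_iter`` iterations.  After fitting, state 1 ("active") is
    always the component with the larger emission mean, whatever order EM
    produced.

    Parameters
    ----------
    n_iter, tol : EM iteration cap (default 500) and log-likelihood
        tolerance (default 1e-6).
    init : {"threshold", "kmeans"}
        Emission initialization.  "threshold" splits intensities at their
        70th percentile (bursting traces spend most frames off, so the
        upper 30% is a robust active-state guess) and falls back to k-means
        when either side of the split is empty or degenerate.
    random_state : seeds the (k-means) initialization; fitting is
        reproducible for a fixed seed.

    Attributes (after ``fit``)
    --------------------------
    means_, sds_ : emission mean and sd per state, index 1 = active.
    transmat_ : 2x2 per-frame transition matrix, rows = from-state.
    startprob_ : initial state distribution.
    """

    def __init__(
        self,
        n_iter: int = 500,
        tol: float = 1e-6,
        init: str = "threshold",
        init_quantile: float = 0.70,
        random_state: int | None = 0,
    ):
        self.n_iter = n_iter
        self.tol = tol
        self.init = init
        self.init_quantile = init_quantile
        self.random_state = random_state

    def _init_means(self, values: np.ndarray) -> np.ndarray | None:
        if self.init == "kmeans":
            return None
        q = np.quantile(values, self.init_quantile)
        lo, hi = values[values <= q], values[values > q]
        if len(lo) == 0 or len(hi) == 0:
            return None
        m = np.array([lo.mean(), hi.mean()])
        if m[0] == m[1]:
            return None
        return m

    def fit(self, traces, y=None):
        """Fit on a long-format trace table or a list of 1-D intensity arrays."""
        if isinstance(traces, pd.DataFrame):
            _, arrays = traces_to_arrays(traces)
        else:
            arrays = [np.asarray(a, dtype=float) for a in traces]
        if len(arrays) == 0:
            raise ValueError("no traces to fit")
        values = np.concatenate(arrays)
        if len(values) < 10:
            raise ValueError("need at least 10 frames in total")
        if np.std(values) == 0:
            raise ValueError("traces have zero variance; emissions are unidentifiable")

        X = values.reshape(-1, 1)
        lengths = [len(a) for a in arrays]
        means0 = self._init_means(values)
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=self.n_iter,
            tol=self.tol,
            random_state=self.random_state,
            init_params="stc" if means0 is not None else "stmc",
        )
        if means0 is not None:
            model.means_ = means0.reshape(-1, 1)
        model.fit(X, lengths)

        order = np.argsort(model.means_.ravel())  # index 1 = larger mean = active
        self.means_ = model.means_.ravel()[order]
        self.sds_ = np.sqrt(model.covars_.ravel()[order])
        self.transmat_ = model.transmat_[np.ix_(order, order)]
        self.startprob_ = model.startprob_[order]
        self._order = order
        self._model = model
        self.monitor_ = model.monitor_
        return self

    def _check_fitted(self):
        if not hasattr(self, "_model"):
            raise ValueError("model is not fitted")
        if not np.all(np.isfinite(self.means_)) or np.any(self.sds_ <= 0):
            raise ValueError("degenerate emission parameters")

    def decode(self, trace: np.ndarray) -> StateSequence:
        """Viterbi path plus per-frame active-state posteriors for one trace."""
        self._check_fitted()
        x = np.asarray(trace, dtype=float).reshape(-1, 1)
        _, raw_states = self._model.decode(x, algorithm="viterbi")
        post = self._model.predict_proba(x)
        inv = np.empty(2, dtype=int)
        inv[self._order] = np.arange(2)  # raw label -> sorted label
        states = inv[raw_states]
        active_col = int(self._order[1])
        return StateSequence(states=states.astype(np.int8), posterior_active=post[:, active_col])

    def predict(self, trace: np.ndarray) -> np.ndarray:
        """Viterbi state path (1 = active) for one trace."""
        return self.decode(trace).states

    def mean_dwell_minutes(self, dt: float) -> dict:
        """Mean dwell times implied by the transition matrix, in minutes.

        For a discrete chain the mean run length in state s is
        1 / (1 - transmat[s, s]) frames.
        """
        self._check_fitted()
        stay = np.diag(self.transmat_)
        frames = 1.0 / np.clip(1.0 - stay, 1e-12, None)
        return {
            "inactive": float(frames[0] * dt / 60.0),
            "active": float(frames[1] * dt / 60.0),
        }


def fit_hmm(traces, **kwargs) -> BurstHMM:
    """Fit a pooled two-state HMM; see :class:`BurstHMM`."""
    return BurstHMM(**kwargs).fit(traces)


def decode(trace: np.ndarray, hmm: BurstHMM) -> StateSequence:
    """Viterbi decoding of one trace with a fitted :class:`BurstHMM`."""
    return hmm.decode(trace)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start, length) for each maximal constant run."""
    states = np.asarray(states)
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(states)]))
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def extract_dwells(states, dt: float = 100.0) -> DwellSummary:
    """Dwell-time summary from one or many decoded state sequences.

    ``states`` is a binary array, a :class:`StateSequence`, or a list of
    either (one entry per allele; dwells are pooled).  Runs are converted to
    minutes (length * dt / 60); runs touching a trace boundary are censored
    and excluded, their count reported.  A trace that never switches
    contributes a single censored run.
    """
    if isinstance(states, StateSequence):
        seqs = [states.states]
    elif isinstance(states, np.ndarray) and states.ndim == 1:
        seqs = [states]
    else:
        seqs = [s.states if isinstance(s, StateSequence) else np.asarray(s) for s in states]
    active, inactive = [], []
    n_censored = 0
    for seq in seqs:
        runs = _runs(seq)
        for k, (state, start, length) in enumerate(runs):
            censored = start == 0 or start + length == len(seq)
            if censored:
                n_censored += 1
                continue
            minutes = length * dt / 60.0
            (active if state == 1 else inactive).append(minutes)
    return DwellSummary(
        active_dwells=np.asarray(active),
        inactive_dwells=np.asarray(inactive),
        n_censored_excluded=n_censored,
        dt=dt,
    )


def dwell_cdf(dwells: np.ndarray) -> pd.DataFrame:
    """Empirical CDF of dwell durations (minutes).

    Returns a table with columns ``duration_min`` (sorted unique values)
    and ``cdf`` = P(dwell <= duration).
    """
    dwells = np.asarray(dwells, dtype=float)
    if len(dwells) == 0:
        raise ValueError("no dwells: empirical CDF undefined")
    xs, counts = np.unique(dwells, return_counts=True)
    cdf = np.cumsum(counts) / len(dwells)
    return pd.DataFrame({"duration_min": xs, "cdf": cdf})
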