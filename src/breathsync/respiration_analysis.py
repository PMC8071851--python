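"""Respiration rate/ratio timeseries extraction and growth-curve fits.

The behavioral pipeline turns a keypress onset log into two
timeseries -- respiration rate (breaths/min) and respiration ratio
(exhale duration / inhale duration) -- via:

1. inter-onset-time (IOT) and per-cycle-ratio streams,
2. a 5-standard-deviation outlier rule against the preceding
   6-keypress window (erroneous presses are discarded and the skipped
   fraction bookkept),
3. a sliding median over 6-keypress windows,
4. linear interpolation onto a 0.1 Hz grid (48 samples per 8-minute
   trial),
5. a natural-log transform and least-squares fit on a fourth-order
   orthonormal polynomial basis, optionally with a per-condition
   design.

The full participant-level mixed-effects machinery is out of scope;
:func:`tidy_table` emits a long-format table ready for any external
mixed-model fitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breath_tracking import OnsetEvent, OnsetKind

WINDOW_KEYPRESSES = 6  # -> 5 IOT values per window
OUTLIER_SD_FACTOR = 5.0
_SD_EPS = 1e-9
GRID_RATE_HZ = 0.1
TRIAL_SECONDS = 480.0


# ------------------------------------------------------------- raw streams


@dataclass
class TrialSeries:
    """One trial's rate or ratio series through the pipeline stages."""

    kind: str  # 'rate' | 'ratio'
    raw_times: np.ndarray
    raw_values: np.ndarray
    kept_mask: np.ndarray
    skipped_fraction: float  # percent
    grid_times: np.ndarray
    grid_values: np.ndarray


def cycle_metrics(
    events: list[OnsetEvent],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-keypress IOT stream and per-cycle exhale:inhale ratio stream.

    Returns ``(iot_times, iots, ratio_times, ratios)``.  IOTs are the
    intervals between consecutive events, stamped at the later event.
    A ratio needs a proper inhale -> exhale -> inhale triple (inhale
    duration = exhale onset - inhale onset; exhale duration = next
    inhale onset - exhale onset), stamped at the closing inhale; a
    missing or doubled press yields no ratio for that cycle.
    """
    if len(events) < 2:
        return (np.array([]),) * 4
    times = np.array([e.time for e in events])
    iots = np.diff(times)
    iot_times = times[1:]

    ratio_times, ratios = [], []
    for i in range(len(events) - 2):
        a, b, c = events[i], events[i + 1], events[i + 2]
        if (
            a.kind is OnsetKind.INHALE
            and b.kind is OnsetKind.EXHALE
            and c.kind is OnsetKind.INHALE
        ):
            inhale = b.time - a.time
            exhale = c.time - b.time
            if inhale > 0:
                ratio_times.append(c.time)
                ratios.append(exhale / inhale)
    return iot_times, iots, np.array(ratio_times), np.array(ratios)


def outlier_filter(
    times: np.ndarray, values: np.ndarray, window: int = WINDOW_KEYPRESSES
) -> tuple[np.ndarray, float]:
    """5-SD rule against the previous window; returns (kept mask, % skipped).

    A value is discarded when it deviates from the mean of the
    preceding window's *surviving* values by more than five times their
    sample standard deviation.  The first window is never discarded.
    Degenerate guard: if that standard deviation is below 1e-9, any
    deviation above 1e-9 is discarded.
    """
    n_prev = window - 1  # values per 6-keypress window
    values = np.asarray(values, dtype=float)
    n = len(values)
    kept = np.ones(n, dtype=bool)
    accepted: list[float] = []
    for i, v in enumerate(values):
        if len(accepted) < n_prev:
            accepted.append(v)
            continue
        prev = np.array(accepted[-n_prev:])
        mu = prev.mean()
        sd = prev.std(ddof=1)
        if sd < _SD_EPS:
            bad = abs(v - mu) > _SD_EPS
        else:
            bad = abs(v - mu) > OUTLIER_SD_FACTOR * sd
        if bad:
            kept[i] = False
        else:
            accepted.append(v)
    skipped = 100.0 * (n - kept.sum()) / n if n else 0.0
    return kept, float(skipped)


def sliding_median(
    events: list[OnsetEvent],
    kept_iot_mask: np.ndarray | None = None,
    window: int = WINDOW_KEYPRESSES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed median IOT and breathing rate over 6-keypress spans.

    Each window covers ``window`` consecutive surviving keypresses
    (hence ``window - 1`` IOT values); its timestamp is the median
    event time of the window.  The rate (breaths/min) counts full
    inhale-to-inhale cycles inside the window:
    ``60 * (n_inhales - 1) / (t_last_inhale - t_first_inhale)``.

    Returns ``(window_times, median_iots, rates)``; rate entries are
    NaN for windows with fewer than two inhale onsets.
    """
    evs = list(events)
    if kept_iot_mask is not None and len(evs) >= 2:
        # Dropping IOT i (between events i and i+1) removes event i+1:
        # the later press of an erroneous interval is the culprit.
        keep_ev = np.ones(len(evs), dtype=bool)
        keep_ev[1:] = kept_iot_mask
        evs = [e for e, k in zip(evs, keep_ev) if k]
    if len(evs) < window:
        return np.array([]), np.array([]), np.array([])

    times = np.array([e.time for e in evs])
    kinds = np.array([e.kind is OnsetKind.INHALE for e in evs])
    w_times, med_iots, rates = [], [], []
    for i in range(len(evs) - window + 1):
        t_win = times[i : i + window]
        w_times.append(float(np.median(t_win)))
        med_iots.append(float(np.median(np.diff(t_win))))
        inh = t_win[kinds[i : i + window]]
        if len(inh) >= 2 and inh[-1] > inh[0]:
            rates.append(60.0 * (len(inh) - 1) / (inh[-1] - inh[0]))
        else:
            rates.append(np.nan)
    return np.array(w_times), np.array(med_iots), np.array(rates)


def resample(
    times: np.ndarray,
    values: np.ndarray,
    rate: float = GRID_RATE_HZ,
    duration: float = TRIAL_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto the t = 0, 1/rate, ... grid.

    A 480 s trial at 0.1 Hz gives exactly 48 samples.  Edge values are
    held constant outside the data span.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    times, values = times[ok], values[ok]
    if len(values) < 2:
        raise ValueError("resampling needs at least 2 surviving points")
    n = int(round(duration * rate))
    grid = np.arange(n) / rate
    return grid, np.interp(grid, times, values)


def extract_series(
    events: list[OnsetEvent],
    kind: str,
    duration: float = TRIAL_SECONDS,
    grid_rate: float = GRID_RATE_HZ,
) -> TrialSeries:
    """Full raw-to-grid pipeline for one trial: filter, median, resample."""
    if kind not in ("rate", "ratio"):
        raise ValueError("kind must be 'rate' or 'ratio'")
    iot_times, iots, ratio_times, ratios = cycle_metrics(events)
    if kind == "rate":
        kept, skipped = outlier_filter(iot_times, iots)
        w_times, _, rates = sliding_median(events, kept_iot_mask=kept)
        raw_times, raw_values = w_times, rates
    else:
        kept, skipped = outlier_filter(ratio_times, ratios)
        raw_times = ratio_times[kept]
        raw_values = ratios[kept]
        # Sliding median over surviving cycle ratios (window of 3 cycles
        # spans ~6 keypresses).
        if len(raw_values) >= 3:
            sm = pd.Series(raw_values).rolling(3, center=True).median()
            raw_values = sm.to_numpy()
    grid_times, grid_values = resample(raw_times, raw_values, grid_rate, duration)
    return TrialSeries(
        kind=kind,
        raw_times=np.asarray(raw_times, dtype=float),
        raw_values=np.asarray(raw_values, dtype=float),
        kept_mask=kept,
        skipped_fraction=skipped,
        grid_times=grid_times,
        grid_values=grid_values,
    )


# ------------------------------------------------------------- growth fits


def orthogonal_basis(n: int = 48, degree: int = 4) -> np.ndarray:
    """Orthonormal polynomial basis on the grid index 0..n-1.

    QR of the Vandermonde matrix of the centered index; columns are
    degrees 0..degree, signs fixed so the constant column is positive
    and the linear column increasing.  B.T @ B = I to machine
    precision.
    """
    if n <= degree:
        raise ValueError("need n > degree grid points")
    x = np.arange(n, dtype=float)
    x = (x - x.mean()) / (n / 2.0)
    V = np.vander(x, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    for j in range(degree + 1):
        # Make each column's leading-order trend positive.
        if Q[-1, j] < Q[0, j] or (j == 0 and Q[0, j] < 0):
            Q[:, j] *= -1.0
    return Q


def design_matrix(basis: np.ndarray) -> np.ndarray:
    """Regression design: ones intercept + orthonormal time terms.

    The orthonormal basis's constant column is rescaled to ones (the
    usual orthogonal-polynomial regression convention), so the fitted
    intercept is the mean log value -- ``log c`` exactly for a constant
    series -- while the higher-order columns stay orthonormal and
    mutually orthogonal to the intercept.
    """
    X = basis.copy()
    X[:, 0] = 1.0
    return X


@dataclass
class GrowthFit:
    """Least-squares growth-curve fit on the log scale."""

    basis_degree: int
    coefficients: np.ndarray  # (degree+1,) or (n_conditions, degree+1)
    standard_errors: np.ndarray
    residuals: np.ndarray
    conditions: list[str] | None = None

    def summary(self) -> pd.DataFrame:
        terms = ["intercept", "linear", "quadratic", "cubic", "quartic"][
            : self.basis_degree + 1
        ]
        if self.conditions is None:
            return pd.DataFrame(
                {"term": terms, "estimate": self.coefficients, "se": self.standard_errors}
            )
        rows = []
        for ci, cond in enumerate(self.conditions):
            for ti, term in enumerate(terms):
                rows.append(
                    {
                        "condition": cond,
                        "term": term,
                        "estimate": self.coefficients[ci, ti],
                        "se": self.standard_errors[ci, ti],
                    }
                )
        return pd.DataFrame(rows)


def fit_growth(
    grid_values: np.ndarray,
    basis: np.ndarray | None = None,
    conditions: list[str] | None = None,
) -> GrowthFit:
    """Natural-log-scale least squares on the orthonormal polynomial basis.

    ``grid_values`` is one series (n,) or a stack of trials (m, n);
    with ``conditions`` (one label per trial) a separate coefficient
    vector is fit per condition by pooled least squares within the
    condition.  All values must be strictly positive.
    """
    y = np.atleast_2d(np.asarray(grid_values, dtype=float))
    bad = np.argwhere(y <= 0)
    if bad.size:
        trial, idx = bad[0]
        raise ValueError(
            f"non-positive value at trial {trial}, grid index {idx}: "
            f"{y[trial, idx]} (log transform undefined)"
        )
    n = y.shape[1]
    if basis is None:
        basis = orthogonal_basis(n=n)
    degree = basis.shape[1] - 1
    logy = np.log(y)
    basis = design_matrix(basis)

    def _ols(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # Y: (k, n) trials; pooled fit of the shared trajectory.
        yy = Y.reshape(-1)
        X = np.tile(basis, (Y.shape[0], 1))
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        dof = max(len(yy) - basis.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return beta, np.sqrt(np.diag(cov)), resid

    if conditions is None:
        beta, se, resid = _ols(logy)
        return GrowthFit(degree, beta, se, resid)

    if len(conditions) != y.shape[0]:
        raise ValueError("one condition label per trial required")
    labels = list(dict.fromkeys(conditions))
    coefs, ses, resids = [], [], []
    for lab in labels:
        mask = np.array([c == lab for c in conditions])
        beta, se, resid = _ols(logy[mask])
        coefs.append(beta)
        ses.append(se)
        resids.append(resid)
    return GrowthFit(
        degree,
        np.vstack(coefs),
        np.vstack(ses),
        np.concatenate(resids),
        conditions=labels,
    )


def tidy_table(
    series_list: list[TrialSeries],
    trial_ids: list[str] | None = None,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format table (trial, condition, grid_time, value, log_value).

    Ready for an external mixed-effects fitter; one row per grid point.
    """
    frames = []
    for i, s in enumerate(series_list):
        frames.append(
            pd.DataFrame(
                {
                    "trial": trial_ids[i] if trial_ids else f"trial{i}",
                    "condition": conditions[i] if conditions else "none",
                    "kind": s.kind,
                    "grid_time": s.grid_times,
                    "value": s.grid_values,
                    "log_value": np.log(s.grid_values),
                    "skipped_fraction": s.skipped_fraction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
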