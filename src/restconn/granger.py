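"""Granger-causality indices for directed (effective) connectivity.

The Granger causality index (GCI) from x to y is
``ln(sigma2_reduced / sigma2_full)`` where ``sigma2_reduced`` is the
residual variance of y regressed on its own ``order`` lags and
``sigma2_full`` additionally includes x's lags.  By the least-squares
nesting property the full model never fits worse, so the population GCI
is non-negative; finite-sample estimates can dip slightly below zero
and are clipped at 0 for reporting (the unclipped value is available
for calibration studies).

A relay-mediated index for a path x -> relay -> y is defined as the
drop in GC when the relay's past is added to both models:
``mediated = max(0, GCI(x->y) - GCI(x->y | relay))`` — large when the
influence of x on y is routed through the relay.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fit_var",
    "gci_pairwise",
    "gci_conditional",
    "gci_mediated",
    "test_gci_nonzero",
    "compare_gci_groups",
    "compute_gci_table",
    "compare_gci_table_groups",
    "select_var_order",
]


def _lagged(series_list, order, t):
    """Design matrix of an intercept plus `order` lags of each series."""
    cols = [np.ones(t - order)]
    for s in series_list:
        for lag in range(1, order + 1):
            cols.append(s[order - lag:t - lag])
    return np.column_stack(cols)


def _resid_var(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid) / len(y)


def fit_var(data, order=1):
    """Least-squares VAR(p) fit with intercept.

    ``data`` is (t, k) with time along axis 0.  Returns
    ``(coefficients, residual_covariance, residuals)`` where
    ``coefficients`` has shape (k, 1 + k*order): the intercept followed
    by lag-1..lag-p coefficient blocks (ordering: series-major, lag-minor
    to match :func:`_lagged`).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("fit_var expects a (t, k) matrix")
    t, k = data.shape
    if t <= order * k + 1:
        raise ValueError(f"too few timepoints ({t}) for a VAR({order}) on {k} "
                         "series; lower the order")
    X = _lagged([data[:, j] for j in range(k)], order, t)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular regressor matrix; try a lower model order")
    Y = data[order:]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma = resid.T @ resid / resid.shape[0]
    return beta.T, sigma, resid


def var_coefficient(coefficients, target, source, lag=1, order=1):
    """Extract the lag-``lag`` coefficient of ``source`` on ``target``."""
    return float(coefficients[target, 1 + source * order + (lag - 1)])


def _check_series(*series, order):
    t = len(series[0])
    for s in series:
        if len(s) != t:
            raise ValueError("all series must have equal length")
    if t <= 3 * order + 3:
        raise ValueError(f"series too short ({t}) for order {order}")
    return t


def gci_pairwise(x, y, order=1, clip=True) -> float:
    """GCI of x -> y: ``ln(var[y | y-lags] / var[y | y-lags, x-lags])``."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    t = _check_series(x, y, order=order)
    target = y[order:t]
    v_red = _resid_var(_lagged([y], order, t), target)
    v_full = _resid_var(_lagged([y, x], order, t), target)
    if v_full <= 0 or v_red <= 0:
        raise ValueError("zero residual variance; y is perfectly predictable")
    g = float(np.log(v_red / v_full))
    return max(0.0, g) if clip else g


def gci_conditional(x, y, relay, order=1, clip=True) -> float:
    """GCI of x -> y conditional on the relay's past (Geweke-style)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    relay = np.asarray(relay, float).ravel()
    t = _check_series(x, y, relay, order=order)
    _check_distinct(x, y, relay)
    target = y[order:t]
    v_red = _resid_var(_lagged([y, relay], order, t), target)
    v_full = _resid_var(_lagged([y, relay, x], order, t), target)
    if v_full <= 0 or v_red <= 0:
        raise ValueError("zero residual variance; y is perfectly predictable")
    g = float(np.log(v_red / v_full))
    return max(0.0, g) if clip else g


def gci_mediated(x, y, relay, order=1) -> float:
    """Relay-mediated GCI: ``max(0, GCI(x->y) - GCI(x->y | relay))``.

    Near the pairwise GCI for a pure chain x -> relay -> y, and near 0
    when the relay is independent of the x -> y path.
    """
    direct = gci_pairwise(x, y, order=order, clip=False)
    conditional = gci_conditional(x, y, relay, order=order, clip=False)
    return max(0.0, direct - conditional)


def _check_distinct(x, y, relay):
    for a, b, names in ((x, relay, "x and relay"), (y, relay, "y and relay"),
                        (x, y, "x and y")):
        if a is b or (a.shape == b.shape and np.array_equal(a, b)):
            raise ValueError(f"{names} must be distinct series")


def select_var_order(data, max_order=5):
    """Bayesian-information-criterion choice of VAR order in 1..max_order."""
    data = np.asarray(data, dtype=float)
    t, k = data.shape
    best, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        if t <= p * k + 1:
            break
        _, sigma, resid = fit_var(data, order=p)
        n_obs = resid.shape[0]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        n_params = k * (1 + k * p)
        bic = n_obs * logdet + n_params * np.log(n_obs)
        if bic < best_bic:
            best, best_bic = p, bic
    return best


# ---------------------------------------------------------------------------
# group-level summaries


def test_gci_nonzero(values):
    """One-sample t-test of a group's GCIs against zero.

    Returns ``(mean, sd, p)`` (two-sided), the per-group summary usually
    reported as ``mean ± sd, p``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 subjects")
    if np.allclose(v, v[0]):
        raise ValueError("zero variance across subjects; t undefined")
    t, p = stats.ttest_1samp(v, 0.0)
    return float(v.mean()), float(v.std(ddof=1)), float(p)


def compare_gci_groups(values_a, values_b):
    """Pooled-variance two-sample t-test; t > 0 when group A's mean is larger."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    if np.var(np.concatenate([a - a.mean(), b - b.mean()])) == 0:
        raise ValueError("zero pooled variance; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compute_gci_table(timecourses_by_subject: dict[str, np.ndarray],
                      order: int = 1, relay: int | None = None,
                      node_names: list[str] | None = None,
                      standardize: bool = True) -> pd.DataFrame:
    """Per-subject GCIs for every ordered node pair (plus mediated paths).

    ``timecourses_by_subject`` maps subject id to a (t, K) matrix of
    component time courses.  If ``relay`` names a node index, mediated
    indices source -> target via relay are added for every ordered pair
    not involving the relay.  Series are standardized before fitting
    (GCI is scale-invariant; standardization stabilises the regression).

    Returns a tidy DataFrame with columns
    ``subject_id, source, target, relay, order, gci``.
    """
    rows = []
    for sid, tc in timecourses_by_subject.items():
        tc = np.asarray(tc, dtype=float)
        k = tc.shape[1]
        names = node_names if node_names is not None else [f"n{j}" for j in range(k)]
        if standardize:
            tc = (tc - tc.mean(0)) / tc.std(0)
        for i, j in itertools.permutations(range(k), 2):
            g = gci_pairwise(tc[:, i], tc[:, j], order=order)
            rows.append((sid, names[i], names[j], "", order, g))
        if relay is not None:
            for i, j in itertools.permutations(range(k), 2):
                if relay in (i, j):
                    continue
                g = gci_mediated(tc[:, i], tc[:, j], tc[:, relay], order=order)
                rows.append((sid, names[i], names[j], names[relay], order, g))
    return pd.DataFrame(rows, columns=["subject_id", "source", "target",
                                       "relay", "order", "gci"])


def compare_gci_table_groups(table: pd.DataFrame, groups: dict[str, str],
                             group_a: str = "patient",
                             group_b: str = "control") -> pd.DataFrame:
    """Per-connection group comparison of a GCI table.

    Returns one row per (source, target, relay) with each group's
    mean ± sd and one-sample p, plus the two-sample t and p
    (t > 0 when ``group_a`` exceeds ``group_b``).
    """
    table = table.copy()
    table["group"] = table["subject_id"].map(groups)
    out = []
    for (src, tgt, rel), sub in table.groupby(["source", "target", "relay"],
                                              sort=False):
        a = sub.loc[sub["group"] == group_a, "gci"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "gci"].to_numpy()
        ma, sa, pa = test_gci_nonzero(a)
        mb, sb, pb = test_gci_nonzero(b)
        t, p = compare_gci_groups(a, b)
        out.append((src, tgt, rel, ma, sa, pa, mb, sb, pb, t, p))
    return pd.DataFrame(out, columns=[
        "source", "target", "relay",
        f"{group_a}_mean", f"{group_a}_sd", f"{group_a}_p",
        f"{group_b}_mean", f"{group_b}_sd", f"{group_b}_p", "t", "p"])
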