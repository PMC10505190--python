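"""One-phase exponential decay fitting of plasmid-cleavage time courses.

Time courses record the fraction of intact circular plasmid remaining at
each sampled time.  Each replicate is fitted separately with
``y(t) = A * exp(-t / tau) + c`` (time-constant parameterization,
``k = 1/tau``); the plateau ``c`` is fixed at zero by default because the
assay consumes substrate with single-turnover kinetics, and can be freed
behind a flag.  Rate constants are summarized per variant/target group
and compared with either Welch's t-test or the Mann-Whitney test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class KineticsError(ValueError):
    pass


@dataclass
class DecayCurve:
    timepoints: np.ndarray  # seconds, strictly increasing
    intact_fraction: np.ndarray  # in [0, 1]
    replicate_id: str = ""
    variant_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.intact_fraction = np.asarray(self.intact_fraction, dtype=float)
        if len(self.timepoints) != len(self.intact_fraction):
            raise KineticsError("timepoints and fractions differ in length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise KineticsError("timepoints must be strictly increasing")
        if np.any((self.intact_fraction < 0) | (self.intact_fraction > 1)):
            raise KineticsError("intact fractions must lie in [0, 1]")


@dataclass
class DecayFit:
    amplitude: float
    k: float  # 1/s; NaN on flagged fits
    plateau: float
    rss: float
    converged: bool
    flag: str = ""
    replicate_id: str = ""
    variant_id: str = ""
    target_id: str = ""

    @property
    def tau(self) -> float:
        return 1.0 / self.k if math.isfinite(self.k) and self.k > 0 else math.nan


def _init_loglinear(t: np.ndarray, y: np.ndarray, plateau: float) -> tuple:
    """Log-linear initial guess for (A, tau) given a plateau estimate."""
    z = y - plateau
    mask = z > 1e-12
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(t[mask], np.log(z[mask]), 1)
        if slope < 0:
            return float(np.exp(intercept)), float(-1.0 / slope)
    span = max(t[-1] - t[0], 1e-9)
    return float(max(z[0], 1e-6)), float(span / 3.0)


def fit_decay(curve: DecayCurve, plateau_mode: str = "fixed0") -> DecayFit:
    """Least-squares fit of a one-phase exponential decay to one replicate.

    ``plateau_mode='fixed0'`` pins the plateau at zero; ``'free'`` fits
    it.  A series with no net decay is returned flagged with ``k`` unset
    rather than forced through the model.  Fewer than 3 timepoints is an
    error.
    """
    if plateau_mode not in ("fixed0", "free"):
        raise KineticsError(f"unknown plateau_mode {plateau_mode!r}")
    t, y = curve.timepoints, curve.intact_fraction
    if len(t) < 3:
        raise KineticsError("need at least 3 timepoints to fit a decay")
    meta = dict(
        replicate_id=curve.replicate_id, variant_id=curve.variant_id, target_id=curve.target_id
    )
    if y[-1] >= y[0] - 1e-12:
        return DecayFit(
            amplitude=math.nan,
            k=math.nan,
            plateau=math.nan,
            rss=math.nan,
            converged=False,
            flag="no decay",
            **meta,
        )

    if plateau_mode == "fixed0":
        a0, tau0 = _init_loglinear(t, y, 0.0)

        def model(tt, a, tau):
            return a * np.exp(-tt / tau)

        p0, bounds = [a0, tau0], ([0.0, 1e-12], [np.inf, np.inf])
    else:
        c0 = float(min(y))
        a0, tau0 = _init_loglinear(t, y, c0)

        def model(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c

        p0, bounds = [a0, tau0, c0], ([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, t, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-14, ftol=1e-14
            )
        converged = True
    except (RuntimeError, ValueError):
        return DecayFit(
            amplitude=math.nan,
            k=math.nan,
            plateau=math.nan,
            rss=math.nan,
            converged=False,
            flag="fit failed",
            **meta,
        )
    resid = y - model(t, *popt)
    plateau = float(popt[2]) if plateau_mode == "free" else 0.0
    return DecayFit(
        amplitude=float(popt[0]),
        k=float(1.0 / popt[1]),
        plateau=plateau,
        rss=float(np.sum(resid**2)),
        converged=converged,
        **meta,
    )


def fit_table(timecourses: pd.DataFrame, plateau_mode: str = "fixed0") -> pd.DataFrame:
    """Fit every (variant, target, replicate) series of a long table.

    Expects columns (variant_id, target_id, replicate, t_seconds,
    intact_fraction); returns one row per fit.
    """
    required = {"variant_id", "target_id", "replicate", "t_seconds", "intact_fraction"}
    if missing := required - set(timecourses.columns):
        raise KineticsError(f"time-course table missing columns {sorted(missing)}")
    rows = []
    for (vid, tid, rep), block in timecourses.groupby(
        ["variant_id", "target_id", "replicate"], sort=False
    ):
        block = block.sort_values("t_seconds")
        fit = fit_decay(
            DecayCurve(
                timepoints=block["t_seconds"].to_numpy(),
                intact_fraction=block["intact_fraction"].to_numpy(),
                replicate_id=str(rep),
                variant_id=str(vid),
                target_id=str(tid),
            ),
            plateau_mode=plateau_mode,
        )
        rows.append(
            {
                "variant_id": vid,
                "target_id": tid,
                "replicate": rep,
                "k": fit.k,
                "amplitude": fit.amplitude,
                "plateau": fit.plateau,
                "rss": fit.rss,
                "converged": fit.converged,
                "flag": fit.flag,
            }
        )
    return pd.DataFrame(rows)


def summarize_rates(fits: pd.DataFrame, grouping: dict | None = None) -> tuple:
    """Mean k per (variant, target) and optional group summaries.

    ``grouping`` maps (variant_id, target_id) -> group label (e.g. an in
    cellulo cleavage category).  Returns (per_pair table, per_group table);
    groups whose every fit failed are omitted with a warning.
    """
    conv = fits[fits["converged"]]
    per_pair = (
        conv.groupby(["variant_id", "target_id"], sort=False)["k"]
        .agg(mean_k="mean", n_fits="count")
        .reset_index()
    )
    if grouping is None:
        return per_pair, pd.DataFrame()
    per_pair = per_pair.assign(
        group=[
            grouping.get((v, t)) for v, t in zip(per_pair["variant_id"], per_pair["target_id"])
        ]
    )
    dropped = sorted(
        {g for g in grouping.values()}
        - set(per_pair.dropna(subset=["group"])["group"].unique())
    )
    if dropped:
        warnings.warn(f"groups with no converged fits omitted: {dropped}", stacklevel=2)
    grp = (
        per_pair.dropna(subset=["group"])
        .groupby("group", sort=False)["mean_k"]
        .agg(
            n="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            mean="mean",
        )
        .reset_index()
    )
    return per_pair, grp


@dataclass
class GroupComparison:
    """Routine two-group statistics (thin wrapper over scipy)."""

    test: str  # "welch-t" or "mann-whitney"
    statistic: float
    pvalue: float
    effect_direction: int  # sign of median(A) - median(B)
    n_a: int
    n_b: int


def compare_rate_groups(
    group_a, group_b, method: str = "auto", alpha_normality: float = 0.05
) -> GroupComparison:
    """Compare two groups of rate constants.

    ``method='auto'`` screens both groups with Shapiro-Wilk and uses
    Welch's two-tailed unpaired t-test when both pass, otherwise the
    two-tailed Mann-Whitney test (exact for small samples).  Groups need
    at least 3 values each.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise KineticsError("each group needs at least 3 values")
    if method == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (
                stats.shapiro(a).pvalue > alpha_normality
                and stats.shapiro(b).pvalue > alpha_normality
            )
        method = "welch" if normal else "mannwhitney"
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "welch-t"
    elif method == "mannwhitney":
        exact = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=exact)
        test = "mann-whitney"
    else:
        raise KineticsError(f"unknown method {method!r}")
    direction = int(np.sign(np.median(a) - np.median(b)))
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        effect_direction=direction,
        n_a=len(a),
        n_b=len(b),
    )
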