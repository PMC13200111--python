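"""Deviation-distribution statistics, factor analyses and tolerance flagging.

The analyses mirror a machine-QA workflow: per-axis deviation histograms with
Gaussian density fits; heteroscedasticity-aware group comparisons (Levene's
test for variance homogeneity, Welch's ANOVA for means under unequal
variances, Games-Howell post hoc pairs); and a moving-window running mean per
delivery session that flags sustained systematic position errors against
TG-224-style tolerances (1 mm annual, 2 mm daily by default; 50-spot window).

Welch's ANOVA follows the classic heteroscedastic F with a
Satterthwaite-type denominator df; Games-Howell uses the studentized-range
reference with Welch-Satterthwaite pairwise df.  Levene's test delegates to
scipy (mean-centered, i.e. the classic variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

FACTOR_COLUMNS = {"energy": "energy", "date": "date", "room": "room"}
RESPONSE_COLUMNS = ("dx", "dy", "d", "dmu")


# --- distribution summaries -------------------------------------------------


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    #: (mu, sigma) of the fitted normal density — the moment fit
    gaussian_fit: tuple[float, float]


def summarize(values) -> DistributionSummary:
    """Moments of a deviation sample; SD uses the n-1 (sample) convention."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("cannot summarise an empty sample")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return DistributionSummary(
        n=int(arr.size),
        mean=mean,
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        gaussian_fit=(mean, sd),
    )


def expected_squared_distance(mu_x: float, sd_x: float, mu_y: float, sd_y: float) -> float:
    """Mean squared Euclidean deviation under independent normal axis errors.

    With dx ~ N(mu_x, sd_x^2) and dy ~ N(mu_y, sd_y^2) independent, the
    squared distance dx^2 + dy^2 is noncentral-chi-square-shaped with mean
    mu_x^2 + sd_x^2 + mu_y^2 + sd_y^2 (mm^2).
    """
    if sd_x < 0 or sd_y < 0:
        raise ValidationError("standard deviations must be >= 0")
    return mu_x**2 + sd_x**2 + mu_y**2 + sd_y**2


# --- heteroscedastic group tests --------------------------------------------


def _as_groups(groups, min_n: int = 2) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(out):
        if g.size < min_n:
            raise ValidationError(f"group {i} has n={g.size} < {min_n}")
    return out


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Classic (mean-centered) Levene test of variance homogeneity.

    Returns ``(W, p)`` with W referred to F(k-1, N-k).
    """
    gs = _as_groups(groups)
    w, p = stats.levene(*gs, center=center)
    return float(w), float(p)


def welch_anova(groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, df1, df2, p)``.  Group weights are n_i / s_i^2; the
    denominator df is the Satterthwaite-type approximation, so groups with
    zero variance are rejected (df undefined).
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.any(v == 0):
        raise ValidationError("Welch's ANOVA is undefined for zero-variance groups")
    w = n / v
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    a = ((w * (m - m_w) ** 2).sum()) / (k - 1)
    tail = ((1.0 - w / w_sum) ** 2 / (n - 1.0)).sum()
    b = 1.0 + (2.0 * (k - 2.0) / (k**2 - 1.0)) * tail
    f_stat = a / b
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * tail)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, float(df2), p


def games_howell(groups, labels=None) -> pd.DataFrame:
    """Games-Howell post hoc pairwise comparisons.

    For each pair: q = |m_i - m_j| / sqrt((s_i^2/n_i + s_j^2/n_j) / 2),
    Welch-Satterthwaite df, p from the studentized range with k groups.
    Returns a DataFrame with columns group_a, group_b, mean_diff, se, df, q, p.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if np.any([g.var(ddof=1) == 0 for g in gs]):
        raise ValidationError("Games-Howell is undefined for zero-variance groups")
    if labels is None:
        labels = list(range(k))
    rows = []
    for i, j in combinations(range(k), 2):
        gi, gj = gs[i], gs[j]
        ni, nj = gi.size, gj.size
        vi, vj = gi.var(ddof=1), gj.var(ddof=1)
        diff = gi.mean() - gj.mean()
        se2 = vi / ni + vj / nj
        q = abs(diff) / np.sqrt(se2 / 2.0)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "se": float(np.sqrt(se2)),
                "df": float(df),
                "q": float(q),
                "p": min(1.0, p),
            }
        )
    return pd.DataFrame(rows)


# --- moving-window tolerance flags ------------------------------------------


@dataclass(frozen=True)
class ToleranceConfig:
    """Spot-position tolerances (mm) and the running-mean window (spots)."""

    annual_mm: float = 1.0
    daily_mm: float = 2.0
    window: int = 50

    def __post_init__(self):
        if not (self.annual_mm > 0 and self.daily_mm > 0):
            raise ValidationError("tolerances must be > 0")
        if not (isinstance(self.window, int) and self.window >= 1):
            raise ValidationError("window must be an integer >= 1")


@dataclass
class SessionFlags:
    """Per-session flag detail: window means and per-spot flags per tier."""

    room: str
    date: object
    n_spots: int
    #: window-level running means, one row per contiguous window
    window_means: pd.DataFrame  # columns: start, end, mean_x, mean_y
    #: per-spot booleans (union over axes): spot is in >=1 exceeding window
    annual: np.ndarray
    daily: np.ndarray
    annual_x: np.ndarray
    annual_y: np.ndarray
    daily_x: np.ndarray
    daily_y: np.ndarray
    affected_layers_annual: list[int]
    affected_layers_daily: list[int]


@dataclass
class FlagReport:
    sessions: dict[tuple, SessionFlags] = field(default_factory=dict)

    def counts(self, tier: str = "annual", axis: str = "union") -> int:
        """Total flagged spots across sessions for a tier ('annual'/'daily')
        and axis ('x', 'y' or the default 'union')."""
        attr = tier if axis == "union" else f"{tier}_{axis}"
        return int(sum(getattr(s, attr).sum() for s in self.sessions.values()))

    @property
    def flagged_sessions(self) -> list[tuple]:
        return [k for k, s in self.sessions.items() if s.annual.any() or s.daily.any()]


def _spots_in_exceeding_windows(values: np.ndarray, window: int, tol: float) -> np.ndarray:
    """Boolean per spot: True iff ANY contiguous ``window``-length window
    containing the spot has |running mean| > tol.  Rolling-sum implementation;
    equivalent to the naive all-windows re-scan."""
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    means = (csum[window:] - csum[:-window]) / window  # window starts 0..n-window
    exceed = np.abs(means) > tol
    flagged = np.zeros(n, dtype=bool)
    if exceed.any():
        # dilate each exceeding window start over its covered spots
        delta = np.zeros(n + 1, dtype=np.int64)
        starts = np.flatnonzero(exceed)
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + window, -1)
        flagged = np.cumsum(delta[:-1]) > 0
    return flagged


def moving_window_flags(table: pd.DataFrame, tol: ToleranceConfig = ToleranceConfig()) -> FlagReport:
    """Flag sustained systematic position errors per session.

    For each (room, date) session the per-axis running mean over every
    contiguous ``tol.window``-spot window (in delivery order, never spanning
    sessions) is compared against the annual and daily tolerances; a spot is
    flagged at a tier if any window covering it exceeds that tier's tolerance
    on either axis.
    """
    report = FlagReport()
    for (room, date), grp in table.groupby(["room", "date"], sort=True):
        dx = grp["dx"].to_numpy()
        dy = grp["dy"].to_numpy()
        layers = grp["layer_index"].to_numpy()
        n = dx.size
        if tol.window > n:
            raise ValidationError(
                f"window {tol.window} larger than session ({room}, {date}) with {n} spots"
            )
        csx = np.concatenate([[0.0], np.cumsum(dx)])
        csy = np.concatenate([[0.0], np.cumsum(dy)])
        w = tol.window
        means = pd.DataFrame(
            {
                "start": np.arange(n - w + 1),
                "end": np.arange(w - 1, n),
                "mean_x": (csx[w:] - csx[:-w]) / w,
                "mean_y": (csy[w:] - csy[:-w]) / w,
            }
        )
        ann_x = _spots_in_exceeding_windows(dx, w, tol.annual_mm)
        ann_y = _spots_in_exceeding_windows(dy, w, tol.annual_mm)
        day_x = _spots_in_exceeding_windows(dx, w, tol.daily_mm)
        day_y = _spots_in_exceeding_windows(dy, w, tol.daily_mm)
        annual = ann_x | ann_y
        daily = day_x | day_y
        report.sessions[(room, date)] = SessionFlags(
            room=room,
            date=date,
            n_spots=n,
            window_means=means,
            annual=annual,
            daily=daily,
            annual_x=ann_x,
            annual_y=ann_y,
            daily_x=day_x,
            daily_y=day_y,
            affected_layers_annual=sorted(np.unique(layers[annual]).tolist()),
            affected_layers_daily=sorted(np.unique(layers[daily]).tolist()),
        )
    return report


# --- factor analysis --------------------------------------------------------


@dataclass
class FactorAnalysisResult:
    factor: str
    response: str
    levels: list
    group_summaries: dict
    levene: tuple[float, float] | None
    welch: tuple[float, float, float, float] | None
    games_howell: pd.DataFrame | None
    skipped: bool = False
    reason: str = ""


def factor_analysis(
    table: pd.DataFrame, factor: str, response: str
) -> FactorAnalysisResult:
    """Run Levene + Welch ANOVA + Games-Howell on deviations grouped by a
    factor (``energy``, ``date`` or ``room``).

    Singleton levels (n < 2) are excluded with a warning; if fewer than two
    usable levels remain the analysis is skipped (``skipped=True``).
    """
    if factor not in FACTOR_COLUMNS:
        raise ValidationError(f"unknown factor {factor!r}; use one of {sorted(FACTOR_COLUMNS)}")
    if response not in RESPONSE_COLUMNS:
        raise ValidationError(f"unknown response {response!r}; use one of {RESPONSE_COLUMNS}")
    col = FACTOR_COLUMNS[factor]
    groups, labels = [], []
    for level, grp in table.groupby(col, sort=True):
        vals = grp[response].to_numpy()
        if vals.size < 2:
            warnings.warn(
                f"factor {factor}: level {level!r} has n={vals.size} < 2; excluded",
                stacklevel=2,
            )
            continue
        groups.append(vals)
        labels.append(level)
    if groups and any(np.var(g, ddof=1) == 0 for g in groups):
        # e.g. an all-zero deviation table: the heteroscedastic tests are
        # undefined, and there is no variability to analyse anyway
        warnings.warn(
            f"factor {factor}: zero-variance group(s); analysis skipped",
            stacklevel=2,
        )
        return FactorAnalysisResult(
            factor, response, labels,
            {lab: summarize(g) for lab, g in zip(labels, groups)},
            None, None, None, skipped=True, reason="zero-variance groups",
        )
    if len(groups) < 2:
        warnings.warn(
            f"factor {factor}: fewer than 2 usable levels; analysis skipped",
            stacklevel=2,
        )
        return FactorAnalysisResult(
            factor, response, labels,
            {lab: summarize(g) for lab, g in zip(labels, groups)},
            None, None, None, skipped=True, reason="fewer than 2 usable levels",
        )
    return FactorAnalysisResult(
        factor=factor,
        response=response,
        levels=labels,
        group_summaries={lab: summarize(g) for lab, g in zip(labels, groups)},
        levene=levene_test(groups),
        welch=welch_anova(groups),
        games_howell=games_howell(groups, labels=labels),
    )
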