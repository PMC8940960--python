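"""FS-14 scoring and the cohort-level nonfatigue-vs-fatigue contrast.

The statistical protocol mirrors standard occupational-HRV practice for
small paired cohorts whose features fail normality screens: a
Lilliefors-corrected Kolmogorov-Smirnov check gates the report toward
nonparametric methods, paired-state association is measured by Spearman
rank correlation, location differences by the two-sided Mann-Whitney U
test, and effect direction by the percent change of group means. The
significance star convention is ``**`` for p < 0.001, ``*`` for
0.001 <= p < 0.05, ``NS`` otherwise. No multiple-testing correction is
applied in the primary table (a clearly labelled supplementary
Holm-Bonferroni column is available on request via ``compare_states``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import HRVError, InsufficientDataError, ParameterError

__all__ = [
    "FS14Record",
    "GroupComparison",
    "DensityEstimate",
    "score_fs14",
    "spearman_rho",
    "mann_whitney_u",
    "ks_normality",
    "percent_change",
    "estimate_pdf",
    "compare_states",
    "stars_for_p",
]

#: Default FS-14 partition: items 1-8 physical, 9-14 mental (0-based indices).
DEFAULT_PHYSICAL_ITEMS = tuple(range(8))
DEFAULT_MENTAL_ITEMS = tuple(range(8, 14))


@dataclass
class FS14Record:
    """A scored 14-item fatigue-scale response (5-point Likert items)."""

    item_scores: tuple[int, ...]
    physical_items: tuple[int, ...] = DEFAULT_PHYSICAL_ITEMS
    mental_items: tuple[int, ...] = DEFAULT_MENTAL_ITEMS
    total: int = 0
    physical: int = 0
    mental: int = 0

    def __post_init__(self) -> None:
        if len(self.item_scores) != 14:
            raise HRVError(f"FS-14 needs 14 items, got {len(self.item_scores)}")
        if any(not 1 <= s <= 5 for s in self.item_scores):
            raise HRVError("FS-14 item scores must be integers in 1..5")
        if set(self.physical_items) & set(self.mental_items):
            raise HRVError("physical and mental item sets overlap")
        self.physical = sum(self.item_scores[i] for i in self.physical_items)
        self.mental = sum(self.item_scores[i] for i in self.mental_items)
        self.total = self.physical + self.mental


def score_fs14(
    items: list[int],
    physical_items: tuple[int, ...] = DEFAULT_PHYSICAL_ITEMS,
    mental_items: tuple[int, ...] = DEFAULT_MENTAL_ITEMS,
) -> FS14Record:
    """Validate 14 Likert items and compute physical/mental/total scores."""
    return FS14Record(
        item_scores=tuple(int(i) for i in items),
        physical_items=physical_items,
        mental_items=mental_items,
    )


def stars_for_p(p: float) -> str:
    """Significance stars: '**' for p < 0.001, '*' for p < 0.05, else 'NS'."""
    if math.isnan(p):
        return "NS"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties; NaN if a
    vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("paired vectors must have equal length")
    if x.size < 3:
        raise InsufficientDataError("Spearman needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def mann_whitney_u(a, b, mode: str = "normal_approx") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts pairs (a_i, b_j) with a_i > b_j
    (ties contribute 1/2), i.e. the U statistic of the first sample.

    ``exact`` enumerates every assignment of the pooled values to the two
    groups (ties handled naturally; limited to n_a + n_b <= 20) and
    defines the two-sided p as the probability of a U at least as far
    from its null mean as observed. ``normal_approx`` uses the normal
    approximation with tie and continuity corrections via scipy.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    u_a = _u_statistic(a, b)
    if mode == "exact":
        if a.size + b.size > 20:
            raise ParameterError("exact mode limited to n_a + n_b <= 20")
        p = _exact_p(a, b, u_a)
    elif mode == "normal_approx":
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    else:
        raise ParameterError(f"unknown mode {mode!r}; use 'exact' or 'normal_approx'")
    return u_a, min(p, 1.0)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{a_i > b_j} + 0.5 * #{a_i == b_j}."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    pooled = np.concatenate([a, b])
    n = pooled.size
    n_a = a.size
    center = a.size * b.size / 2.0
    dev_obs = abs(u_obs - center)
    hits = 0
    total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        # tiny epsilon guards float ties in |U - center|
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def ks_normality(x) -> tuple[float, float]:
    """Lilliefors-corrected one-sample K-S test against a fitted normal.

    Mean and SD are estimated from the data, so the Lilliefors null
    distribution is the correct reference. Returns ``(statistic, p)``;
    a constant sample yields ``(nan, nan)`` (degenerate marker).
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("normality screen needs at least 5 values")
    if np.ptp(x) == 0:
        return math.nan, math.nan
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def percent_change(
    nonfatigue_mean: float, fatigue_mean: float, decimals: int | None = 2
) -> float:
    """Percent change from the nonfatigue to the fatigue group mean.

    ``100 * (fatigue - nonfatigue) / nonfatigue``; NaN on a zero baseline.
    Rounded to ``decimals`` places (None to skip rounding).
    """
    if nonfatigue_mean == 0:
        return math.nan
    rate = 100.0 * (fatigue_mean - nonfatigue_mean) / nonfatigue_mean
    return round(rate, decimals) if decimals is not None else rate


@dataclass
class DensityEstimate:
    """Gaussian-kernel density of one feature for one (gender, state) cell."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    label: str = ""
    point_mass: float | None = None  # set for zero-variance input


def estimate_pdf(
    values, bandwidth_rule: str = "silverman", n_grid: int = 512, label: str = ""
) -> DensityEstimate:
    """Gaussian KDE on a grid spanning the data +- 3 bandwidths.

    The density is renormalized so its trapezoidal integral over the grid
    is exactly 1. Zero-variance input returns a point-mass marker instead
    of a curve.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("density estimation needs at least 5 values")
    if not np.all(np.isfinite(x)):
        raise ParameterError("density estimation requires finite values")
    if np.ptp(x) == 0:
        return DensityEstimate(
            grid=np.array([x[0]]), density=np.array([math.inf]),
            bandwidth=0.0, label=label, point_mass=float(x[0]),
        )
    kde = sps.gaussian_kde(x, bw_method=bandwidth_rule)
    bandwidth = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, n_grid)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=bandwidth, label=label)


@dataclass
class GroupComparison:
    """Per-feature summary of the nonfatigue-vs-fatigue contrast."""

    feature: str
    nonfatigue_mean: float
    nonfatigue_sd: float
    fatigue_mean: float
    fatigue_sd: float
    spearman: float
    u_statistic: float
    p_value: float
    stars: str
    percent_change: float
    n_nonfatigue: int = 0
    n_fatigue: int = 0
    low_n: bool = False
    p_adjusted: float = math.nan  # supplementary Holm-Bonferroni, not primary

    def as_row(self) -> dict:
        return {
            "Parameter": self.feature,
            "Nonfatigue mean": self.nonfatigue_mean,
            "Nonfatigue SD": self.nonfatigue_sd,
            "Fatigue mean": self.fatigue_mean,
            "Fatigue SD": self.fatigue_sd,
            "Spearman": self.spearman,
            "U": self.u_statistic,
            "p": self.p_value,
            "Sig": self.stars,
            "Rate (%)": self.percent_change,
        }


def compare_states(
    features: pd.DataFrame,
    feature_columns: list[str] | None = None,
    stratify_gender: bool = False,
    adjust: bool = True,
) -> pd.DataFrame:
    """Contrast paired nonfatigue/fatigue feature rows across a cohort.

    Parameters
    ----------
    features : DataFrame
        One row per (subject, state) with columns ``subject_id``,
        ``state`` ('nonfatigue'/'fatigue'), optionally ``gender``, plus
        numeric feature columns.
    feature_columns : list of str, optional
        Defaults to every numeric column except identifiers.
    stratify_gender : bool
        When True, produce one comparison block per gender (rows gain a
        ``gender`` column); genders absent from the data are skipped.
    adjust : bool
        Also emit a supplementary Holm-Bonferroni adjusted p column.

    Returns
    -------
    DataFrame
        One row per feature (per gender when stratified) with group
        means/SDs, Spearman rho over within-subject pairs, Mann-Whitney
        U and p, stars, and percent change. Invariant to row order and
        subject relabeling. Features whose pairing is incomplete are
        flagged in the ``note`` column rather than dropped.
    """
    required = {"subject_id", "state"}
    if not required.issubset(features.columns):
        raise ParameterError(f"feature table must have columns {sorted(required)}")
    states = set(features["state"].unique())
    if not states.issubset({"nonfatigue", "fatigue"}):
        raise ParameterError(f"unknown states {states - {'nonfatigue', 'fatigue'}}")
    if feature_columns is None:
        skip = {"subject_id", "state", "gender"}
        feature_columns = [
            c for c in features.columns
            if c not in skip and pd.api.types.is_numeric_dtype(features[c])
        ]

    if stratify_gender:
        if "gender" not in features.columns:
            raise ParameterError("stratify_gender requires a 'gender' column")
        blocks = []
        for gender, sub in features.groupby("gender", sort=True):
            block = _compare_block(sub, feature_columns, adjust)
            block.insert(0, "gender", gender)
            blocks.append(block)
        return pd.concat(blocks, ignore_index=True)
    return _compare_block(features, feature_columns, adjust)


def _compare_block(
    features: pd.DataFrame, feature_columns: list[str], adjust: bool
) -> pd.DataFrame:
    non = features[features["state"] == "nonfatigue"].set_index("subject_id")
    fat = features[features["state"] == "fatigue"].set_index("subject_id")
    # canonical subject order makes the result invariant to row order
    paired_ids = sorted(set(non.index) & set(fat.index))
    rows = []
    for feat in feature_columns:
        a = non[feat].dropna() if feat in non else pd.Series(dtype=float)
        b = fat[feat].dropna() if feat in fat else pd.Series(dtype=float)
        note = ""
        if len(a) < 2 or len(b) < 2:
            rows.append(_empty_row(feat, len(a), len(b), "insufficient data"))
            continue
        pair_a = non.loc[paired_ids, feat].to_numpy(dtype=float)
        pair_b = fat.loc[paired_ids, feat].to_numpy(dtype=float)
        pair_ok = np.isfinite(pair_a) & np.isfinite(pair_b)
        if pair_ok.sum() >= 3:
            rho = spearman_rho(pair_a[pair_ok], pair_b[pair_ok])
        else:
            rho, note = math.nan, "incomplete pairing"
        u, p = mann_whitney_u(a.to_numpy(), b.to_numpy(), mode="normal_approx")
        gc = GroupComparison(
            feature=feat,
            nonfatigue_mean=float(a.mean()),
            nonfatigue_sd=float(a.std(ddof=1)),
            fatigue_mean=float(b.mean()),
            fatigue_sd=float(b.std(ddof=1)),
            spearman=rho,
            u_statistic=u,
            p_value=p,
            stars=stars_for_p(p),
            percent_change=percent_change(float(a.mean()), float(b.mean())),
            n_nonfatigue=len(a),
            n_fatigue=len(b),
            low_n=min(len(a), len(b)) < 5,
        )
        row = gc.as_row()
        row["n nonfatigue"] = gc.n_nonfatigue
        row["n fatigue"] = gc.n_fatigue
        row["low_n"] = gc.low_n
        row["note"] = note
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust and "p" in out.columns:
        out["p (Holm, supplementary)"] = _holm(out["p"].to_numpy(dtype=float))
    return out


def _empty_row(feat: str, n_a: int, n_b: int, note: str) -> dict:
    return {
        "Parameter": feat,
        "Nonfatigue mean": math.nan, "Nonfatigue SD": math.nan,
        "Fatigue mean": math.nan, "Fatigue SD": math.nan,
        "Spearman": math.nan, "U": math.nan, "p": math.nan,
        "Sig": "NS", "Rate (%)": math.nan,
        "n nonfatigue": n_a, "n fatigue": n_b, "low_n": True, "note": note,
    }


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (NaNs passed through)."""
    out = np.full_like(p, math.nan, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        adj[i] = min(running, 1.0)
    out[ok] = adj
    return out
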