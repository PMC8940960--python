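"""Nonlinear HRV descriptors: Poincare-plot geometry and sample entropy.

The Poincare plot scatters each RR interval against its successor; SD1 and
SD2 are the dispersions of the points across and along the identity line.
SD1 equals (sqrt2/2) * SDSD exactly. The classical closed form for SD2,
sqrt(2*SDNN^2 - SDSD^2/2), holds exactly when the variances are taken over
the lag-1 pair ensemble (first/last N-1 intervals and their covariance);
this module computes SD1/SD2 by direct projection and cross-checks them
against that closed form at 1e-9 relative tolerance on every call.

Sample entropy is the negative log conditional probability that template
vectors matching for m points (Chebyshev distance <= r, self-matches
excluded) also match for m+1 points. Defaults: m=2, r = 0.2 * series SD,
delay tau=1 — the standard short-term HRV parameterization.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, InternalConsistencyError, ParameterError
from .types import PoincareSummary, RRSeries, SampEnResult, require_min_intervals

__all__ = ["poincare_descriptors", "sample_entropy", "entropy_panel"]

SQRT2_OVER_2 = math.sqrt(2.0) / 2.0


def poincare_descriptors(rr: RRSeries, ddof: int = 0) -> PoincareSummary:
    """SD1/SD2 ellipse descriptors of the Poincare plot.

    Projections of the (RR_i, RR_{i+1}) cloud onto the directions
    perpendicular and parallel to y = x give SD1 and SD2 directly (the
    parallel axis is the line y = -x + 2*meanRR; its offset cancels in a
    standard deviation). ``ratio`` is NaN for a constant series.
    """
    require_min_intervals(rr, 3, "Poincare analysis")
    x = rr.intervals[:-1]
    y = rr.intervals[1:]
    points = np.column_stack([x, y])

    # transverse / longitudinal projections (rotation by 45 degrees)
    p_t = (y - x) * SQRT2_OVER_2
    p_l = (y + x) * SQRT2_OVER_2
    sd1 = float(p_t.std(ddof=ddof))
    sd2 = float(p_l.std(ddof=ddof))

    _check_closed_forms(x, y, sd1, sd2, ddof)

    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    return PoincareSummary(sd1=sd1, sd2=sd2, ratio=ratio, points=points)


def _check_closed_forms(
    x: np.ndarray, y: np.ndarray, sd1: float, sd2: float, ddof: int
) -> None:
    """Cross-check projections against the SDSD/SDNN closed forms.

    Over the pair ensemble: SD1^2 = Var(y-x)/2 and
    SD2^2 = 2 * (Var(x)+Var(y))/2 ... - Var(y-x)/2 reduces to
    (Var(x)+Var(y))/2 + Cov(x, y), which the identity
    sqrt(2*SDNN^2 - SDSD^2/2) expresses with SDNN^2 read as the pooled
    pair variance.
    """
    sdsd2 = np.var(y - x, ddof=ddof)
    pooled = 0.5 * (np.var(x, ddof=ddof) + np.var(y, ddof=ddof))
    sd1_cf = math.sqrt(0.5 * sdsd2)
    rad = 2.0 * pooled - 0.5 * sdsd2
    if rad < -1e-9 * max(pooled, 1.0):
        raise InternalConsistencyError("negative SD2 radicand")
    sd2_cf = math.sqrt(max(rad, 0.0))
    scale = max(sd1, sd2, 1.0)
    if abs(sd1 - sd1_cf) > 1e-9 * scale or abs(sd2 - sd2_cf) > 1e-9 * scale:
        raise InternalConsistencyError(
            f"Poincare projection vs closed form disagree: "
            f"sd1 {sd1} vs {sd1_cf}, sd2 {sd2} vs {sd2_cf}"
        )


def sample_entropy(
    series: Sequence[float] | np.ndarray,
    m: int = 2,
    r_coef: float = 0.2,
    tau: int = 1,
    r: float | None = None,
) -> SampEnResult:
    """Sample entropy of a numeric series.

    Parameters
    ----------
    series : sequence of float
        Length must be at least ``m * tau + 10``.
    m : int
        Embedding dimension of the template vectors.
    r_coef : float
        Tolerance as a fraction of the series SD, in (0, 1). Ignored when
        ``r`` is given.
    tau : int
        Embedding delay in samples.
    r : float, optional
        Absolute tolerance in series units; overrides ``r_coef``. When the
        series is constant (SD = 0) and no ``r`` is given, the tolerance
        falls back to a tiny absolute floor so the entropy is 0 rather
        than an error.

    Returns
    -------
    SampEnResult
        ``value = ln(phi_m / phi_m1)`` where phi_k is the mean fraction of
        non-self template pairs within tolerance at order k. NaN when no
        pair matches at order m+1.

    Notes
    -----
    Both orders use the same N - m*tau template vectors, so the entropy is
    a true conditional-probability estimate. Distances are Chebyshev,
    comparison is ``<= r``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if m < 1 or tau < 1:
        raise ParameterError("m and tau must be positive integers")
    if n < m * tau + 10:
        raise InsufficientDataError(
            f"series of length {n} too short for m={m}, tau={tau}"
        )
    if r is None:
        if not 0 < r_coef < 1:
            raise ParameterError("r_coef must be in (0, 1)")
        sd = float(x.std(ddof=0))
        # absolute floor keeps a constant series well-defined (entropy 0)
        r = max(r_coef * sd, 1e-12)
    else:
        sd = float(x.std(ddof=0))
        r_coef = r / sd if sd > 0 else math.nan

    n_templates = n - m * tau  # templates for which the (m+1)-point vector exists
    if n_templates < 2:
        raise InsufficientDataError("fewer than 2 template vectors")

    # delay-embedded matrices, orders m and m+1, over the same template set
    emb_m = _embed(x, m, tau, n_templates)
    emb_m1 = _embed(x, m + 1, tau, n_templates)

    b = _match_count(emb_m, r)    # pairs within r at order m
    a = _match_count(emb_m1, r)   # pairs within r at order m+1

    pairs = n_templates * (n_templates - 1) / 2.0
    phi_m = b / pairs
    phi_m1 = a / pairs
    value = math.log(phi_m / phi_m1) if a > 0 and b > 0 else math.nan

    return SampEnResult(
        m=m, tau=tau, r=float(r), r_coef=float(r_coef),
        phi_m=phi_m, phi_m1=phi_m1, value=value, n=n,
    )


def _embed(x: np.ndarray, order: int, tau: int, n_templates: int) -> np.ndarray:
    idx = np.arange(n_templates)[:, None] + tau * np.arange(order)[None, :]
    return x[idx]


def _match_count(emb: np.ndarray, r: float) -> int:
    """Number of unordered template pairs with Chebyshev distance <= r."""
    n = emb.shape[0]
    count = 0
    # row-blocked broadcasting keeps memory bounded for long records
    block = max(1, 2_000_000 // max(emb.size, 1))
    for start in range(0, n - 1, block):
        stop = min(start + block, n - 1)
        chunk = emb[start:stop, None, :]          # (b, 1, m)
        rest = emb[None, start + 1:, :]           # (1, n-start-1, m)
        d = np.abs(chunk - rest).max(axis=2)      # (b, n-start-1)
        # keep only j > i within this chunk
        rows = np.arange(start, stop)[:, None]
        cols = np.arange(start + 1, n)[None, :]
        count += int(np.sum((d <= r) & (cols > rows)))
    return count


def entropy_panel(
    rr: RRSeries, m: int = 2, r_coef: float = 0.2, tau: int = 1
) -> dict[str, SampEnResult | None]:
    """Sample entropy of the RR, instantaneous-HR and R-peak-amplitude series.

    Returns a dict with keys ``SampleEn_RR``, ``SampleEn_iHR`` and
    ``SampleEn_Peak``; the peak channel is None when the series carries no
    amplitudes.
    """
    from .ecg import instantaneous_hr

    panel: dict[str, SampEnResult | None] = {}
    panel["SampleEn_RR"] = sample_entropy(rr.intervals, m=m, r_coef=r_coef, tau=tau)
    panel["SampleEn_iHR"] = sample_entropy(
        instantaneous_hr(rr), m=m, r_coef=r_coef, tau=tau
    )
    if rr.amplitudes is not None:
        panel["SampleEn_Peak"] = sample_entropy(
            rr.amplitudes, m=m, r_coef=r_coef, tau=tau
        )
    else:
        panel["SampleEn_Peak"] = None
    return panel
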