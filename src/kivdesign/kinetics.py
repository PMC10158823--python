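"""Batch-culture kinetics and group comparison.

During unrestricted exponential growth dX/dt = mu * X, so the maximum
specific growth rate mu_max (1/h) is the ordinary least-squares slope of
ln X against time over the exponential window. Yield coefficients are
endpoint ratios over the batch:

    Yx/s = dX/dS   (g DCW per g substrate)
    Yp/s = dP/dS   (g product per g substrate)
    Yp/x = dP/dX   (g product per g DCW)

Biomass is measured as OD600 and converted to dry cell weight with the
strain-specific correlation g DCW/L = 0.452 * OD600.

Conditions are compared with Duncan's multiple range test: an ANOVA-pooled
error variance, studentized-range critical values at the protected level
1 - (1-alpha)^(p-1) for a span of p ordered means, and the conventional
letter display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

#: OD600 -> g dry cell weight per litre for E. coli W.
OD_TO_DCW_FACTOR = 0.452


def od_to_dcw(od600: float) -> float:
    """Convert an OD600 reading to g DCW/L (0.452 g DCW/L per OD unit)."""
    if od600 < 0:
        raise ValueError("OD600 must be non-negative")
    return od600 * OD_TO_DCW_FACTOR


def linear_calibration(signal, concentration) -> tuple[float, float, float]:
    """Generic least-squares calibration line: returns (slope, intercept, R^2).

    Utility for external-standard curves (HPLC areas, colorimetric
    absorbances); the chemistry itself is out of scope.
    """
    res = stats.linregress(np.asarray(signal, float), np.asarray(concentration, float))
    return res.slope, res.intercept, res.rvalue**2


@dataclass
class MuMaxFit:
    """Log-linear growth-rate fit over one window."""

    mu_max: float  # 1/h
    r_squared: float
    window: tuple[int, int]  # [start, stop) indices into the curve
    n_points: int


@dataclass
class KineticParams:
    """Full kinetic characterisation of one batch culture."""

    mu_max: float
    Yxs: float
    Yps: float
    Ypx: float
    r_squared: float
    window: tuple[int, int]


def detect_exponential_phase(t, X, min_points: int = 4) -> tuple[int, int]:
    """Find the contiguous window of >= min_points maximising R^2 of ln X vs t.

    Only strictly positive biomass readings can enter a window. Windows
    tying in R^2 (within 1e-9) prefer more points, then the earliest
    start — so a perfectly exponential curve returns its full range.
    Returns (start, stop) as a half-open index window.
    """
    t = np.asarray(t, float)
    X = np.asarray(X, float)
    if min_points < 3:
        raise ValueError("min_points must be >= 3 for a meaningful regression")
    n = len(t)
    best: tuple[float, int, int] | None = None  # (r2, length, -start) maximised
    for start in range(n):
        for stop in range(start + min_points, n + 1):
            xs = X[start:stop]
            ts = t[start:stop]
            if np.any(xs <= 0):
                continue
            if np.ptp(ts) == 0:
                continue
            lnx = np.log(xs)
            if np.ptp(lnx) == 0:
                r2 = 0.0  # a flat stretch (lag/plateau) is not growth
            else:
                r2 = stats.linregress(ts, lnx).rvalue ** 2
            key = (round(r2 / 1e-9) * 1e-9, stop - start, -start)
            if best is None or key > best[:3]:
                best = (*key[:3], start, stop)
    if best is None:
        raise ValueError(
            f"no window of {min_points} positive biomass readings available"
        )
    return best[3], best[4]


def fit_mu_max(t, X, window: tuple[int, int] | None = None, min_points: int = 4) -> MuMaxFit:
    """mu_max as the OLS slope of ln X on t over the exponential window.

    With ``window=None`` the window is detected first. Rescaling X by any
    positive constant leaves the slope unchanged.
    """
    t = np.asarray(t, float)
    X = np.asarray(X, float)
    if window is None:
        window = detect_exponential_phase(t, X, min_points=min_points)
    start, stop = window
    ts, xs = t[start:stop], X[start:stop]
    if len(ts) < 2 or np.ptp(ts) == 0:
        raise ValueError("window has no time variance")
    if np.any(xs <= 0):
        raise ValueError("window contains non-positive biomass")
    lnx = np.log(xs)
    if np.allclose(lnx, lnx[0]):
        return MuMaxFit(mu_max=0.0, r_squared=1.0, window=window, n_points=len(ts))
    res = stats.linregress(ts, lnx)
    return MuMaxFit(
        mu_max=float(res.slope),
        r_squared=float(res.rvalue**2),
        window=window,
        n_points=len(ts),
    )


def compute_yields(delta_X: float, delta_S: float, delta_P: float) -> tuple[float, float, float]:
    """Endpoint yields (Yxs, Yps, Ypx) from batch increments.

    ``delta_S`` is substrate consumed (> 0), ``delta_X`` biomass formed,
    ``delta_P`` product formed. Degenerate denominators raise, naming the
    affected yield.
    """
    if delta_S <= 0:
        raise ValueError("Yx/s and Yp/s undefined: substrate consumed must be > 0")
    if delta_X <= 0:
        raise ValueError("Yp/x undefined: biomass formed must be > 0")
    return delta_X / delta_S, delta_P / delta_S, delta_P / delta_X


def characterize_culture(t, X, S, P, min_points: int = 4) -> KineticParams:
    """Growth rate plus endpoint yields for one culture time series."""
    fit = fit_mu_max(t, X, min_points=min_points)
    S = np.asarray(S, float)
    X = np.asarray(X, float)
    P = np.asarray(P, float)
    yxs, yps, ypx = compute_yields(X[-1] - X[0], S[0] - S[-1], P[-1] - P[0])
    return KineticParams(
        mu_max=fit.mu_max,
        Yxs=yxs,
        Yps=yps,
        Ypx=ypx,
        r_squared=fit.r_squared,
        window=fit.window,
    )


# --------------------------------------------------------------------------
# Duncan's multiple range test
# --------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Result of a multiple-range comparison across condition means."""

    labels: list[str]
    means: dict[str, float]
    letters: dict[str, str]  # groups sharing a letter are not distinguishable
    mse: float
    df_error: int
    alpha: float

    def letter_table(self) -> str:
        lines = [f"{'group':<20s} {'mean':>12s}  letters"]
        for lab in sorted(self.means, key=self.means.get, reverse=True):
            lines.append(f"{lab:<20s} {self.means[lab]:>12.5g}  {self.letters[lab]}")
        return "\n".join(lines)


@lru_cache(maxsize=256)
def _duncan_critical(p: int, df: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protected level for span p."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


def duncan_mrt(
    groups: list[np.ndarray],
    alpha: float = 0.05,
    labels: list[str] | None = None,
) -> GroupComparison:
    """Duncan's multiple range test with the standard letter display.

    ``groups`` are replicate vectors (>= 2 each). The error variance is
    the ANOVA pooled within-group mean square; unequal group sizes use the
    harmonic mean n (a documented approximation). For each span p of
    ordered means, the least significant range is
    q(1 - alpha_p, p, df) * sqrt(MSE / n_h) with the protection level
    alpha_p = 1 - (1-alpha)^(p-1); a range inside a non-significant
    stretch is never declared significant (containment rule). With k = 2
    groups the procedure reduces exactly to Fisher's LSD at alpha.

    Edge case: zero pooled variance makes every nonzero mean difference
    significant (and equal means never significant).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 replicates")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match groups")

    n_total = sum(len(g) for g in groups)
    df_error = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_error
    n_h = k / sum(1.0 / len(g) for g in groups)  # harmonic mean group size
    se = np.sqrt(mse / n_h)

    means = np.array([g.mean() for g in groups])
    order = np.argsort(-means)  # descending
    sorted_means = means[order]

    # nonsig[i][j]: ordered means i..j (i<j) not significantly different
    nonsig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            # containment: inside an already non-significant stretch
            covered = any(
                nonsig[a][b] for a in range(0, i + 1) for b in range(j, k) if (a, b) != (i, j)
            )
            if covered:
                nonsig[i][j] = True
                continue
            diff = sorted_means[i] - sorted_means[j]
            if se == 0.0:
                significant = diff > 0.0
            else:
                significant = diff > _duncan_critical(span, df_error, alpha) * se
            nonsig[i][j] = not significant

    # letter display from maximal non-significant stretches
    stretches: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i][j + 1]:
            j += 1
        stretches.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in set(stretches)
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in stretches)
    ]
    maximal.sort()
    letter_of: dict[int, str] = {}
    alphabet = string.ascii_lowercase
    for rank, (i, j) in enumerate(maximal):
        letter = alphabet[rank % len(alphabet)]
        for pos in range(i, j + 1):
            letter_of[pos] = letter_of.get(pos, "") + letter

    letters = {labels[order[pos]]: letter_of[pos] for pos in range(k)}
    return GroupComparison(
        labels=list(labels),
        means={lab: float(m) for lab, m in zip(labels, means)},
        letters=letters,
        mse=float(mse),
        df_error=df_error,
        alpha=alpha,
    )
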