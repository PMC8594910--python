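"""Statistical battery for the threshold-vs-current-density analysis.

Nonparametric tests as applied to phosphene thresholds across montages:
one-tailed Spearman rank correlation between thresholds and simulated
current densities (exact permutation p for small n), Pearson regression for
the density and electrode-distance relationships, Friedman's two-factorial
rank ANOVA for the montage effect, Bonferroni-corrected Wilcoxon signed-rank
post hocs (exact tie-aware null), and the Mann-Whitney U test for the
eye-dominance contrast.  Every result is a :class:`StatsResult` carrying the
statistic, p-value, sidedness and correction so reports stay auditable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi_summary import electrode_eye_distances

__all__ = [
    "StatsResult",
    "spearman",
    "pearson_regression",
    "friedman",
    "wilcoxon_signed_rank",
    "wilcoxon_pairwise",
    "mann_whitney",
    "distance_analysis",
]


@dataclass
class StatsResult:
    method: str
    n: int
    statistic: float
    p: float
    sided: str = "two-sided"
    estimates: dict = field(default_factory=dict)
    correction: str = "none"
    m_comparisons: int = 1
    p_corrected: float | None = None
    provenance: str = ""

    def __post_init__(self):
        for key in ("r", "r_s", "r2"):
            if key in self.estimates:
                v = self.estimates[key]
                lo = 0.0 if key == "r2" else -1.0
                if not (lo - 1e-12 <= v <= 1.0 + 1e-12):
                    raise ValueError(f"{key} = {v} out of range")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n": self.n,
            "statistic": self.statistic,
            "p": self.p,
            "sided": self.sided,
            "correction": self.correction,
        }
        d.update(self.estimates)
        if self.p_corrected is not None:
            d["p_corrected"] = self.p_corrected
            d["m"] = self.m_comparisons
        return d


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

EXACT_SPEARMAN_MAX_N = 8


def spearman(x, y, sided: str = "two-sided", provenance: str = "") -> StatsResult:
    """Spearman rank correlation with average-rank ties.

    For n ≤ 8 the p-value is exact, from the full n! permutation null of the
    rank correlation (ties kept fixed); larger samples use the t
    approximation.  ``sided`` is ``"two-sided"``, ``"greater"`` (positive
    association) or ``"less"``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx, ry = _rank(x), _rank(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size

    if n <= EXACT_SPEARMAN_MAX_N:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        vals = np.array(
            [float(rx_c @ np.array(p)) for p in itertools.permutations(ry_c)]
        ) / denom
        eps = 1e-12
        if sided == "greater":
            p = float((vals >= rs - eps).mean())
        elif sided == "less":
            p = float((vals <= rs + eps).mean())
        else:
            p = float((np.abs(vals) >= abs(rs) - eps).mean())
        method = "spearman (exact permutation)"
    else:
        if abs(rs) == 1.0:
            p_two = 0.0
        else:
            t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
            p_two = 2.0 * float(sps.t.sf(abs(t), n - 2))
        if sided == "two-sided":
            p = p_two
        else:
            one = p_two / 2.0
            toward = (rs >= 0 and sided == "greater") or (rs < 0 and sided == "less")
            p = one if toward else 1.0 - one
        method = "spearman (t approximation)"
    return StatsResult(
        method=method, n=n, statistic=rs, p=p, sided=sided,
        estimates={"r_s": rs}, provenance=provenance,
    )


def pearson_regression(x, y, provenance: str = "") -> StatsResult:
    """Least-squares line with Pearson r, r² and the two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("regression undefined for zero-variance input")
    res = sps.linregress(x, y)
    r = float(res.rvalue)
    return StatsResult(
        method="pearson regression",
        n=x.size,
        statistic=r,
        p=float(res.pvalue),
        estimates={
            "r": r,
            "r2": r * r,
            "slope": float(res.slope),
            "intercept": float(res.intercept),
        },
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def friedman(pt_matrix, exact: bool = False, provenance: str = "") -> StatsResult:
    """Friedman rank ANOVA over a complete subjects × montages matrix.

    The chi-square statistic uses within-subject average ranks with tie
    correction (matching the standard SPSS/scipy convention).  With
    ``exact=True`` the p-value is the permutation probability over all
    (k!)^n within-row orderings (feasible for small matrices only).
    """
    X = np.asarray(pt_matrix, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and montages")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed")
    n, k = X.shape

    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2, p_asym = sps.friedmanchisquare(*[X[:, j] for j in range(k)])
        chi2, p_asym = float(chi2), float(p_asym)
    except (ValueError, ZeroDivisionError):
        chi2, p_asym = 0.0, 1.0
    if not np.isfinite(chi2):  # fully tied rows: no variation to test
        chi2, p_asym = 0.0, 1.0

    if not exact:
        return StatsResult(
            method="friedman (chi-square approximation)", n=n,
            statistic=chi2, p=p_asym, estimates={"df": k - 1},
            provenance=provenance,
        )

    total = math.factorial(k) ** n
    if total > 2_000_000:
        raise ValueError("matrix too large for the exact permutation null")

    def chi2_of(mat) -> float:
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                c, _ = sps.friedmanchisquare(*[mat[:, j] for j in range(k)])
            c = float(c)
            return c if np.isfinite(c) else 0.0
        except (ValueError, ZeroDivisionError):
            return 0.0

    count = 0
    perms = list(itertools.permutations(range(k)))
    for combo in itertools.product(perms, repeat=n):
        mat = np.vstack([X[i, list(pi)] for i, pi in enumerate(combo)])
        if chi2_of(mat) >= chi2 - 1e-12:
            count += 1
    return StatsResult(
        method="friedman (exact permutation)", n=n, statistic=chi2,
        p=count / total, estimates={"df": k - 1}, provenance=provenance,
    )


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float, sided: str) -> float:
    """Exact signed-rank tail via DP over the 2× (integer) rank sums."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(w2))
    p_ge = float(dist[w2:].sum())
    p_le = float(dist[: w2 + 1].sum())
    if sided == "greater":
        return p_ge
    if sided == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_signed_rank(
    x, y=None, sided: str = "two-sided", exact_max_n: int = 20,
    provenance: str = "",
) -> StatsResult:
    """Wilcoxon signed-rank test (paired), tie-aware.

    Zero differences are dropped; tied |differences| get average ranks; the
    statistic is W⁺, the positive-rank sum.  For n ≤ ``exact_max_n`` the
    p-value is exact (all 2ⁿ sign assignments, ties honored); otherwise the
    normal approximation with tie correction is used.  ``sided="greater"``
    tests for x > y.
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test degenerate")
    ranks = _rank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        p = _signed_rank_exact_p(np.round(ranks * 2), w_plus * 2, sided)
        method = "wilcoxon signed-rank (exact)"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie = float((counts**3 - counts).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
        z = (w_plus - mu) / math.sqrt(var)
        if sided == "greater":
            p = float(sps.norm.sf(z))
        elif sided == "less":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2 * sps.norm.sf(abs(z)))
        method = "wilcoxon signed-rank (normal approximation)"
    return StatsResult(
        method=method, n=n, statistic=w_plus, p=p, sided=sided,
        provenance=provenance,
    )


def wilcoxon_pairwise(
    pt_matrix: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    m: int | None = None,
    sided: str = "two-sided",
) -> list[StatsResult]:
    """Bonferroni-corrected pairwise signed-rank tests over montage columns.

    ``pairs`` defaults to all column pairs; ``m`` (the Bonferroni factor)
    defaults to the number of comparisons actually performed.
    """
    cols = list(pt_matrix.columns)
    if pairs is None:
        pairs = list(itertools.combinations(cols, 2))
    if m is None:
        m = len(pairs)
    out = []
    for a, b in pairs:
        try:
            res = wilcoxon_signed_rank(
                pt_matrix[a].to_numpy(), pt_matrix[b].to_numpy(), sided=sided,
                provenance=f"{a} vs {b}",
            )
        except ValueError:
            # identical columns: no evidence either way, keep the battery going
            res = StatsResult(
                method="wilcoxon signed-rank (degenerate: all ties)",
                n=len(pt_matrix), statistic=0.0, p=1.0, sided=sided,
                provenance=f"{a} vs {b}",
            )
        res.correction = "bonferroni"
        res.m_comparisons = m
        res.p_corrected = min(1.0, m * res.p)
        out.append(res)
    return out


def mann_whitney(
    group_a, group_b, sided: str = "two-sided", provenance: str = ""
) -> StatsResult:
    """Mann-Whitney U for two independent groups (exact when feasible)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and a.size + b.size <= 25) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=sided, method=method)
    return StatsResult(
        method=f"mann-whitney U ({method})",
        n=a.size + b.size,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        sided=sided,
        estimates={"n_a": a.size, "n_b": b.size},
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Distance analysis
# ---------------------------------------------------------------------------

DISTANCE_EXCLUDED_MONTAGE = "So-rS"


def distance_analysis(
    phantom,
    montages: dict[str, "object"],
    pt_summary: dict[str, float],
    oc_roi: np.ndarray,
    exclude: tuple[str, ...] = (DISTANCE_EXCLUDED_MONTAGE,),
) -> dict[str, StatsResult]:
    """Pearson r² of thresholds vs electrode-eye and electrode-OC distance.

    ``pt_summary`` maps montage -> threshold (µA).  The So-rS montage is
    excluded (its eye and occipital current densities are outliers by
    construction of the montage).  Raises if fewer than 3 montages remain.
    """
    keep = [mname for mname in montages if mname not in exclude
            and mname in pt_summary]
    if len(keep) < 3:
        raise ValueError("fewer than 3 montages remain after exclusion")
    eye_d, oc_d, pts = [], [], []
    for mname in keep:
        d = electrode_eye_distances(phantom, montages[mname], oc_roi=oc_roi)
        eye_d.append(d["eye_cm"])
        oc_d.append(d["oc_cm"])
        pts.append(pt_summary[mname])
    return {
        "eye_distance": pearson_regression(
            eye_d, pts, provenance=f"PT vs eye distance, montages={keep}"
        ),
        "oc_distance": pearson_regression(
            oc_d, pts, provenance=f"PT vs OC distance, montages={keep}"
        ),
    }
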