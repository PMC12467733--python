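"""Statistical suite for the measurement-error comparison.

Screening (Shapiro–Wilk normality, mean-centered Levene homogeneity) and the
per-system zero-bias tests (one-sample t, exact Wilcoxon signed rank) feed a
rank-based omnibus design: the tie-corrected Kruskal–Wallis test with the
epsilon-squared effect size

    eps^2 = (H - k + 1) / (N - k),

followed by Dunn's post hoc mean-rank-difference comparisons with Sidak
family-wise adjustment p_adj = 1 - (1 - p_raw)^m and simultaneous
confidence intervals MRD +/- z_{1 - alpha'/2} * SE with
alpha' = 1 - (1 - alpha)^{1/m}.

The Wilcoxon signed-rank p-value is exact for n <= 25: the full
2^n signed-rank distribution is evaluated by a generating-function
convolution over the (doubled, hence integer) midranks, which is identical
to explicit sign enumeration.  Larger samples fall back to the normal
approximation with tie correction.  Shapiro–Wilk, Levene and the t test are
delegated to scipy.stats (Royston AS R94 for Shapiro–Wilk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "OmnibusResult",
    "PairwiseComparison",
    "StatsError",
    "shapiro_wilk",
    "levene",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "dunn_sidak",
    "sidak_adjust",
]

EXACT_WILCOXON_MAX_N = 25


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError("p-value outside [0, 1]")


@dataclass(frozen=True)
class OmnibusResult:
    H: float
    df: int
    p_value: float
    epsilon_sq: float
    mean_ranks: dict
    group_sizes: dict
    tie_sum: float  # sum over tie groups of (t^3 - t)

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes.values()))

    @property
    def k(self) -> int:
        return len(self.group_sizes)


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    mrd: float
    se: float
    z: float
    p_raw: float
    p_adj: float
    ci: tuple[float, float]

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adj < alpha


# ---------------------------------------------------------------------------
# screening and per-system tests (scipy-backed)
# ---------------------------------------------------------------------------

def shapiro_wilk(sample) -> TestResult:
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise StatsError("Shapiro–Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise StatsError("W undefined for a constant sample")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "shapiro-wilk", (x.size,))


def levene(groups, center: str = "mean") -> TestResult:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise StatsError("Levene needs >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in gs):
        raise StatsError("all deviations are zero; Levene undefined")
    res = sps.levene(*gs, center=center)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"levene({center})", tuple(g.size for g in gs))


def one_sample_t(sample, mu0: float = 0.0) -> TestResult:
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise StatsError("t test needs n >= 2")
    if np.ptp(x) == 0:
        raise StatsError("zero variance; t undefined")
    res = sps.ttest_1samp(x, mu0)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "one-sample t", (x.size,))


# ---------------------------------------------------------------------------
# exact Wilcoxon signed rank
# ---------------------------------------------------------------------------

def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts over achievable W+ values (on the doubled-rank scale) of the
    2^n equiprobable sign assignments, by polynomial convolution."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(sample, mu0: float = 0.0) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of median mu0.

    Exact (full 2^n distribution) for n <= 25 after dropping zeros, with
    midranks for tied magnitudes; normal approximation with tie correction
    above.  The statistic reported is W+ (sum of positive ranks).
    """
    x = np.asarray(sample, dtype=float) - mu0
    x = x[x != 0.0]
    n = x.size
    if n < 1:
        raise StatsError("all values equal mu0; Wilcoxon undefined")
    ranks = sps.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(doubled)
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        lower = dist[: w2 + 1].sum() / total
        upper = dist[w2:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        method = "wilcoxon signed rank (exact)"
    else:
        mean = n * (n + 1) / 4.0
        ties = np.unique(ranks, return_counts=True)[1]
        var = (n * (n + 1) * (2 * n + 1) / 24.0
               - ((ties**3 - ties).sum()) / 48.0)
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "wilcoxon signed rank (normal approx.)"
    return TestResult(w_plus, float(p), method, (n,))


# ---------------------------------------------------------------------------
# Kruskal–Wallis omnibus and Dunn–Sidak post hoc
# ---------------------------------------------------------------------------

def _group_items(groups):
    if isinstance(groups, dict):
        return list(groups.items())
    return [(i, g) for i, g in enumerate(groups)]


def kruskal_wallis(groups) -> OmnibusResult:
    """Tie-corrected Kruskal–Wallis H on k groups, with the rank-based
    epsilon-squared effect size and the group mean ranks retained for the
    Dunn post hoc.  ``groups`` is a dict name -> sample or a sequence."""
    items = _group_items(groups)
    k = len(items)
    if k < 2:
        raise StatsError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for _, g in items]
    if any(a.size == 0 for a in arrays):
        raise StatsError("empty group")
    sizes = [a.size for a in arrays]
    n_total = int(sum(sizes))
    if n_total < k + 1:
        raise StatsError("need total N >= k + 1")

    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    mean_ranks, pos = {}, 0
    h = 0.0
    for (name, _), a in zip(items, arrays):
        r = ranks[pos:pos + a.size]
        pos += a.size
        mean_ranks[name] = float(r.mean())
        h += a.size * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    ties = np.unique(pooled, return_counts=True)[1]
    tie_sum = float((ties.astype(float)**3 - ties).sum())
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0:
        raise StatsError("all pooled values tied; H undefined")
    h /= correction

    p = float(sps.chi2.sf(h, k - 1))
    eps_sq = (h - k + 1) / (n_total - k)
    return OmnibusResult(
        H=float(h), df=k - 1, p_value=p, epsilon_sq=float(eps_sq),
        mean_ranks=mean_ranks,
        group_sizes={name: int(a.size) for (name, _), a in zip(items, arrays)},
        tie_sum=tie_sum,
    )


def sidak_adjust(p_raw: float, m: int) -> float:
    """Family-wise Sidak adjustment over m comparisons."""
    if not 0.0 <= p_raw <= 1.0:
        raise StatsError("p_raw outside [0, 1]")
    if m < 1:
        raise StatsError("m must be >= 1")
    return float(np.clip(1.0 - (1.0 - p_raw) ** m, 0.0, 1.0))


def dunn_sidak(omnibus: OmnibusResult, alpha: float = 0.05) -> list[PairwiseComparison]:
    """Dunn's post hoc mean-rank comparisons with Sidak adjustment.

    For groups i, j: MRD = rbar_i - rbar_j, SE includes the standard tie
    correction

        SE = sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)],

    z = MRD / SE with a two-sided normal p, Sidak-adjusted over the
    m = k(k-1)/2 comparisons; the simultaneous CI uses
    alpha' = 1 - (1 - alpha)^(1/m).
    """
    names = list(omnibus.group_sizes)
    k = len(names)
    m = k * (k - 1) // 2
    if m == 0:
        raise StatsError("no pairwise comparisons for k < 2")
    n = omnibus.n_total
    base_var = n * (n + 1) / 12.0 - omnibus.tie_sum / (12.0 * (n - 1))
    alpha_prime = 1.0 - (1.0 - alpha) ** (1.0 / m)
    z_crit = float(sps.norm.ppf(1.0 - alpha_prime / 2.0))

    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = float(np.sqrt(base_var * (1.0 / omnibus.group_sizes[a]
                                           + 1.0 / omnibus.group_sizes[b])))
            mrd = omnibus.mean_ranks[a] - omnibus.mean_ranks[b]
            z = mrd / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            out.append(PairwiseComparison(
                pair=(a, b), mrd=float(mrd), se=se, z=float(z),
                p_raw=p_raw, p_adj=sidak_adjust(p_raw, m),
                ci=(float(mrd - z_crit * se), float(mrd + z_crit * se)),
            ))
    return out
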