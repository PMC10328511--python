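"""Two-level hierarchical bootstrap inference for nested imaging data.

Neurons (or axon-segment ROIs) recorded at the same imaging site are not
independent; treating them as such inflates type-I error.  The
hierarchical bootstrap respects the nesting: each replicate first draws
imaging sites with replacement (as many as observed), pools the values
of the drawn sites, then draws values with replacement from that pool
(as many as pooled), and computes the statistic — repeated 10,000 times
by default.  p-values are proportions of the replicate distribution on
the null side of zero (or of a second distribution), floored at
1/n_boot.  For data whose experimental unit is a field of view or a
mouse, classical flat tests are used instead, with normality
(Shapiro–Wilk) and variance (Levene) pre-checks selecting between
t-tests and rank-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import DEFAULTS


@dataclass
class NestedSample:
    """Per-unit values with site (and optional mouse) grouping."""

    values: np.ndarray
    site_ids: np.ndarray
    mouse_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.site_ids = np.asarray(self.site_ids)
        if self.values.size == 0:
            raise ValueError("empty sample")
        if self.values.shape != self.site_ids.shape:
            raise ValueError("every value needs a site_id")
        if self.mouse_ids is not None:
            self.mouse_ids = np.asarray(self.mouse_ids)
            if self.mouse_ids.shape != self.values.shape:
                raise ValueError("mouse_ids must align with values")

    def by_site(self) -> list:
        return [self.values[self.site_ids == s] for s in np.unique(self.site_ids)]

    def sites_by_mouse(self) -> list:
        """Unique site labels grouped by mouse (requires mouse_ids)."""
        if self.mouse_ids is None:
            raise ValueError("sample has no mouse_ids")
        out = []
        for m in np.unique(self.mouse_ids):
            out.append(list(np.unique(self.site_ids[self.mouse_ids == m])))
        return out


@dataclass
class BootstrapDistribution:
    """Replicate statistic values with provenance."""

    stats: np.ndarray
    n_boot: int
    seed: int
    grouping: str = "site/unit"

    def __post_init__(self):
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.stats) != self.n_boot:
            raise ValueError("length of stats must equal n_boot")


def hier_boot(
    sample: NestedSample,
    statistic=np.mean,
    n_boot: int = DEFAULTS["n_boot"],
    seed: int = 0,
    mouse_level: bool = False,
) -> BootstrapDistribution:
    """Two-level (site → unit) bootstrap distribution of a statistic.

    Per replicate: draw len(sites) sites with replacement, pool their
    values (with multiplicity), draw len(pool) values with replacement
    from the pool, apply ``statistic``.  The second-level resample size
    follows the drawn sites, so replicates dominated by large sites are
    larger — the site draw, not the original total, sets the count.

    ``mouse_level=True`` (requires ``sample.mouse_ids``) prepends a
    third layer: mice are drawn with replacement first and the site
    draw happens within the pooled sites of the drawn mice.  Off by
    default; the standard procedure for neuron-level data resamples
    sites and neurons only.
    """
    site_labels = list(np.unique(sample.site_ids))
    groups = {s: sample.values[sample.site_ids == s] for s in site_labels}
    n_sites = len(site_labels)
    mice = sample.sites_by_mouse() if mouse_level else None
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        if mouse_level:
            drawn_mice = rng.integers(0, len(mice), size=len(mice))
            pool_sites = [s for m in drawn_mice for s in mice[m]]
            sites = [pool_sites[i] for i in rng.integers(0, len(pool_sites), size=len(pool_sites))]
        else:
            sites = [site_labels[i] for i in rng.integers(0, n_sites, size=n_sites)]
        pooled = np.concatenate([groups[s] for s in sites])
        idx = rng.integers(0, len(pooled), size=len(pooled))
        out[b] = statistic(pooled[idx])
    grouping = "mouse/site/unit" if mouse_level else "site/unit"
    return BootstrapDistribution(out, n_boot, seed, grouping=grouping)


def pooled_boot(
    values: np.ndarray,
    statistic=np.mean,
    n_boot: int = DEFAULTS["n_boot"],
    seed: int = 0,
) -> BootstrapDistribution:
    """Flat (grouping-blind) bootstrap, the comparison baseline that
    ignores the nested structure."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return BootstrapDistribution(statistic(values[idx], axis=1), n_boot, seed, grouping="pooled")


def _floor_p(p: float, n_boot: int) -> float:
    return max(p, 1.0 / n_boot)


def p_vs_zero(dist: BootstrapDistribution, alternative: str = "two-sided") -> float:
    """Proportion of the replicate distribution on the null side of zero.

    alternative="greater" tests mean > 0 (p = prop ≤ 0), "less" tests
    mean < 0 (p = prop ≥ 0); "two-sided" doubles the smaller tail,
    capped at 1.  Zero proportions are reported as 1/n_boot, never 0.
    """
    s = dist.stats
    p_le = float(np.mean(s <= 0))
    p_ge = float(np.mean(s >= 0))
    if alternative == "greater":
        return _floor_p(p_le, dist.n_boot)
    if alternative == "less":
        return _floor_p(p_ge, dist.n_boot)
    if alternative == "two-sided":
        return _floor_p(min(2 * min(p_le, p_ge), 1.0), dist.n_boot)
    raise ValueError(f"unknown alternative {alternative!r}")


def p_two_sample(
    dist_a: BootstrapDistribution,
    dist_b: BootstrapDistribution,
    alternative: str = "two-sided",
    all_pairs: bool = False,
) -> float:
    """Proportion of replicate comparisons with A on the null side of B.

    Default pairs replicates by index (prop of A−B on the null side),
    which matches the all-pairs proportion in expectation at O(n_boot)
    cost; ``all_pairs=True`` computes the exact all-pairs proportion
    (quadratic, for small n_boot).
    """
    if all_pairs:
        a = np.sort(dist_a.stats)
        b = dist_b.stats
        # P(A <= B) over all pairs via searchsorted
        p_le = float(np.mean(np.searchsorted(a, b, side="right"))) / len(a)
        p_ge = 1.0 - float(np.mean(np.searchsorted(a, b, side="left"))) / len(a)
        n = min(dist_a.n_boot, dist_b.n_boot)
    else:
        if dist_a.n_boot != dist_b.n_boot:
            raise ValueError("index pairing needs equal n_boot; use all_pairs=True")
        d = dist_a.stats - dist_b.stats
        p_le = float(np.mean(d <= 0))
        p_ge = float(np.mean(d >= 0))
        n = dist_a.n_boot
    if alternative == "greater":
        return _floor_p(p_le, n)
    if alternative == "less":
        return _floor_p(p_ge, n)
    if alternative == "two-sided":
        return _floor_p(min(2 * min(p_le, p_ge), 1.0), n)
    raise ValueError(f"unknown alternative {alternative!r}")


def hier_boot_slope(
    x: np.ndarray,
    y: np.ndarray,
    site_ids: np.ndarray,
    n_boot: int = DEFAULTS["n_boot"],
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[BootstrapDistribution, float]:
    """Bootstrap distribution of the OLS slope of y on x over resampled
    units, plus the p-value for the negative-slope test.

    Resampling follows hier_boot (sites then units, each with
    replacement); a replicate whose resampled x is constant is redrawn.
    p (for the alternative "slope < 0") is the proportion of replicate
    slopes exceeding zero, floored at 1/n_boot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    site_ids = np.asarray(site_ids)
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    sites = np.unique(site_ids)
    gx = [x[site_ids == s] for s in sites]
    gy = [y[site_ids == s] for s in sites]
    n_sites = len(sites)
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_redraws):
            drawn = rng.integers(0, n_sites, size=n_sites)
            px = np.concatenate([gx[s] for s in drawn])
            py = np.concatenate([gy[s] for s in drawn])
            idx = rng.integers(0, len(px), size=len(px))
            bx, by = px[idx], py[idx]
            if np.ptp(bx) > 0:
                break
        else:
            raise RuntimeError("could not draw a replicate with non-constant x")
        bxc = bx - bx.mean()
        out[b] = float(bxc @ (by - by.mean()) / (bxc @ bxc))
    dist = BootstrapDistribution(out, n_boot, seed)
    p_negative = _floor_p(float(np.mean(out > 0)), n_boot)
    return dist, p_negative


def flat_test(group_a, group_b=None, paired: bool = False, alpha_checks: float = 0.05):
    """Classical test for FoV- or mouse-level data with automatic selection.

    One-sample (group_b=None) or paired data: Shapiro–Wilk on the values
    (differences) selects a paired/one-sample t-test vs a signed-rank
    test.  Unpaired: Shapiro–Wilk on both groups plus Levene's variance
    check select Student's t vs the rank-sum test.  Returns
    (test_name, statistic, p).
    """
    a = np.asarray(group_a, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 observations per group")
    if group_b is None or paired:
        d = a if group_b is None else a - np.asarray(group_b, dtype=float)
        if d.size < 3:
            raise ValueError("need at least 3 paired observations")
        normal = sps.shapiro(d).pvalue > alpha_checks
        if normal:
            res = sps.ttest_1samp(d, 0.0)
            name = "paired t-test" if group_b is not None else "one-sample t-test"
        else:
            res = sps.wilcoxon(d)
            name = "signed-rank"
        return name, float(res.statistic), float(res.pvalue)
    b = np.asarray(group_b, dtype=float)
    if b.size < 3:
        raise ValueError("need at least 3 observations per group")
    normal = sps.shapiro(a).pvalue > alpha_checks and sps.shapiro(b).pvalue > alpha_checks
    equal_var = sps.levene(a, b).pvalue > alpha_checks
    if normal and equal_var:
        res = sps.ttest_ind(a, b)
        name = "t-test"
    else:
        res = sps.ranksums(a, b)
        name = "rank-sum"
    return name, float(res.statistic), float(res.pvalue)
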