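"""f-statistics with sample-size bias correction and block-jackknife errors.

f2(A,B) is the expected squared allele-frequency difference between two
populations, f3(X;A,B) the expected product (pX-pA)(pX-pB), and
f4(A,B;C,D) the expected product (pA-pB)(pC-pD); all are estimated as
means of per-SNP terms over the SNPs where every involved population has
a defined frequency ("complete cases"), with standard errors from a
weighted delete-one-block jackknife over contiguous genomic blocks.

Finite samples inflate (pA-pB)^2 by the sampling variance of each
frequency estimate; the unbiased estimators subtract h/c per population,
where h = p(1-p) * c/(c-1) estimates heterozygosity from c observed
allele copies.  f4 terms are products of independent differences and
need no correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import BlockPartition, FreqTable

__all__ = [
    "FStat", "BiplotRow", "block_jackknife", "block_jackknife_cov",
    "estimate_f2", "estimate_f3", "estimate_f4", "drift_biplot",
]


@dataclass
class FStat:
    """A single f-statistic estimate with jackknife uncertainty."""

    kind: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        pops = ",".join(self.populations)
        return (f"{self.kind}({pops}) = {self.estimate:.6g} +- {self.se:.3g} "
                f"(Z = {self.z:.2f}, {self.n_snps} SNPs, {self.n_blocks} blocks)")


@dataclass
class BiplotRow:
    """One test population in the outgroup-f3 shared-drift biplot."""

    test_population: str
    x: float
    y: float
    x_se: float
    y_se: float
    fitted_y: float
    deviation: float
    deviation_se: float


# ---------------------------------------------------------------------------
# jackknife core

def block_jackknife(block_estimates: np.ndarray, block_weights: np.ndarray) -> tuple[float, float]:
    """Weighted delete-one-block jackknife mean and standard error.

    ``block_estimates[j]`` is the statistic computed from block j alone and
    ``block_weights[j]`` its weight (here: SNP count).  The returned mean is
    the weighted whole-data estimate; the SE uses the weighted jackknife
    with unequal block sizes (pseudovalue form).
    """
    theta_j = np.asarray(block_estimates, dtype=float)
    m = np.asarray(block_weights, dtype=float)
    if theta_j.shape != m.shape or theta_j.ndim != 1:
        raise ValueError("block_estimates and block_weights must be equal-length vectors")
    if (m <= 0).any():
        raise ValueError("block weights must be positive")
    g = theta_j.size
    if g < 2:
        raise ValueError("need >= 2 blocks for a jackknife variance")
    n = m.sum()
    theta = float((m * theta_j).sum() / n)
    loo = (n * theta - m * theta_j) / (n - m)  # delete-one estimates
    h = n / m
    tau = h * theta - (h - 1.0) * loo  # pseudovalues
    theta_bc = g * theta - float(((1.0 - m / n) * loo).sum())
    var = float((np.square(tau - theta_bc) / (h - 1.0)).sum() / g)
    return theta, np.sqrt(max(var, 0.0))


def block_jackknife_cov(block_estimates: np.ndarray, block_weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vector-valued weighted block jackknife: mean vector and covariance.

    ``block_estimates`` is g x d.  The diagonal of the returned covariance
    reproduces :func:`block_jackknife` exactly per component.
    """
    theta_j = np.asarray(block_estimates, dtype=float)
    m = np.asarray(block_weights, dtype=float)
    g, _ = theta_j.shape
    if g < 2:
        raise ValueError("need >= 2 blocks for a jackknife covariance")
    n = m.sum()
    theta = (m[:, None] * theta_j).sum(axis=0) / n
    loo = (n * theta[None, :] - m[:, None] * theta_j) / (n - m)[:, None]
    h = n / m
    tau = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo
    theta_bc = g * theta - ((1.0 - m / n)[:, None] * loo).sum(axis=0)
    dev = tau - theta_bc[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / g
    return theta, cov


# ---------------------------------------------------------------------------
# per-SNP terms

def _complete_cases(F: FreqTable, idx: np.ndarray) -> np.ndarray:
    return (F.total[idx] > 0).all(axis=0)


def _hc_term(F: FreqTable, i: int, mask: np.ndarray) -> np.ndarray:
    """h/c = p(1-p)/(c-1): the sampling-variance correction for population i."""
    c = F.total[i, mask].astype(float)
    p = F.count1[i, mask] / c
    return p * (1.0 - p) / np.maximum(c - 1.0, 1.0)


def f2_terms(F: FreqTable, A: str, B: str, corrected: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP f2 terms and the complete-case mask (over all SNPs)."""
    ia, ib = F.index_of([A, B])
    mask = _complete_cases(F, np.array([ia, ib]))
    p = F.freq
    terms = np.square(p[ia, mask] - p[ib, mask])
    if corrected:
        terms = terms - _hc_term(F, ia, mask) - _hc_term(F, ib, mask)
    return terms, mask


def f3_terms(F: FreqTable, X: str, A: str, B: str, corrected: bool = True) -> tuple[np.ndarray, np.ndarray]:
    ix, ia, ib = F.index_of([X, A, B])
    mask = _complete_cases(F, np.array([ix, ia, ib]))
    p = F.freq
    terms = (p[ix, mask] - p[ia, mask]) * (p[ix, mask] - p[ib, mask])
    if corrected:
        terms = terms - _hc_term(F, ix, mask)
    return terms, mask


def f4_terms(F: FreqTable, A: str, B: str, C: str, D: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib, ic, id_ = F.index_of([A, B, C, D])
    mask = _complete_cases(F, np.array([ia, ib, ic, id_]))
    p = F.freq
    terms = (p[ia, mask] - p[ib, mask]) * (p[ic, mask] - p[id_, mask])
    return terms, mask


def _jackknife_stat(kind: str, pops: tuple[str, ...], terms: np.ndarray, mask: np.ndarray,
                    blocks: BlockPartition) -> FStat:
    if terms.size == 0:
        raise ValueError(f"{kind}{pops}: no SNPs with defined frequencies in every population")
    block_id = blocks.block_of[mask]
    sums = np.bincount(block_id, weights=terms, minlength=blocks.n_blocks)
    counts = np.bincount(block_id, minlength=blocks.n_blocks)
    live = counts > 0
    if live.sum() < 2:
        raise ValueError(f"{kind}{pops}: need >= 2 non-empty blocks")
    est, se = block_jackknife(sums[live] / counts[live], counts[live])
    z = est / se if se > 0 else 0.0
    return FStat(kind, pops, est, se, z, int(live.sum()), int(counts.sum()))


# ---------------------------------------------------------------------------
# public estimators

def estimate_f2(F: FreqTable, A: str, B: str, blocks: BlockPartition,
                corrected: bool = True) -> FStat:
    """f2(A,B): squared frequency difference in drift units."""
    if A == B:
        raise ValueError("f2 requires two distinct populations")
    terms, mask = f2_terms(F, A, B, corrected)
    return _jackknife_stat("f2", (A, B), terms, mask, blocks)


def estimate_f3(F: FreqTable, X: str, A: str, B: str, blocks: BlockPartition,
                corrected: bool = True) -> FStat:
    """f3(X;A,B): shared drift of A and B seen from X (outgroup-f3), or
    an admixture test for X when A,B flank it (significantly negative)."""
    if len({X, A, B}) != 3:
        raise ValueError("f3 requires three distinct populations")
    terms, mask = f3_terms(F, X, A, B, corrected)
    return _jackknife_stat("f3", (X, A, B), terms, mask, blocks)


def estimate_f4(F: FreqTable, A: str, B: str, C: str, D: str,
                blocks: BlockPartition) -> FStat:
    """f4(A,B;C,D): covariance of the (A-B) and (C-D) frequency contrasts."""
    if A == B or C == D:
        raise ValueError("f4 requires distinct members within each pair")
    terms, mask = f4_terms(F, A, B, C, D)
    return _jackknife_stat("f4", (A, B, C, D), terms, mask, blocks)


# ---------------------------------------------------------------------------
# outgroup-f3 biplot

def drift_biplot(F: FreqTable, outgroup: str, refA: str, refB: str,
                 tests: list[str], trend_set: list[str],
                 blocks: BlockPartition) -> list[BiplotRow]:
    """Shared-drift biplot of f3(outgroup; refA, t) vs f3(outgroup; refB, t).

    An ordinary least-squares trend line is fitted over ``trend_set``;
    each test population's deviation is y - fitted_y with SE propagated
    from the jackknife SEs of x and y (x-y covariance ignored).
    """
    if not set(trend_set) <= set(tests):
        raise ValueError("trend_set must be a subset of tests")
    if len(trend_set) < 3:
        raise ValueError("need >= 3 trend populations to fit a line")
    stats = {}
    for t in tests:
        sx = estimate_f3(F, outgroup, refA, t, blocks)
        sy = estimate_f3(F, outgroup, refB, t, blocks)
        stats[t] = (sx.estimate, sy.estimate, sx.se, sy.se)
    xs = np.array([stats[t][0] for t in trend_set])
    ys = np.array([stats[t][1] for t in trend_set])
    if np.ptp(xs) == 0.0 or np.var(xs) == 0.0:
        raise ValueError("degenerate trend set: zero variance in x")
    slope, intercept = np.polyfit(xs, ys, 1)
    rows = []
    for t in tests:
        x, y, x_se, y_se = stats[t]
        fitted = slope * x + intercept
        dev_se = float(np.sqrt(y_se ** 2 + slope ** 2 * x_se ** 2))
        rows.append(BiplotRow(t, x, y, x_se, y_se, float(fitted), float(y - fitted), dev_se))
    return rows


def plot_drift_biplot(rows: list[BiplotRow], ax=None, label_points: bool = True):
    """Render a biplot table with its trend line on a matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xs = np.array([r.x for r in rows])
    ys = np.array([r.y for r in rows])
    fitted = np.array([r.fitted_y for r in rows])
    order = np.argsort(xs)
    ax.plot(xs[order], fitted[order], "-", color="grey", lw=1)
    ax.errorbar(xs, ys, xerr=[r.x_se for r in rows], yerr=[r.y_se for r in rows],
                fmt="o", ms=4, lw=0.8)
    if label_points:
        for r in rows:
            ax.annotate(r.test_population, (r.x, r.y), fontsize=7,
                        textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("shared drift with reference A (f3)")
    ax.set_ylabel("shared drift with reference B (f3)")
    return ax
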