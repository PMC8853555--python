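"""Rank tests for ancestry streams and admixture-proportion estimation.

Both tests consume one object: the matrix of f4-statistics
X[i, j] = f4(l0, l_i; r0, r_j) between a "left" set (target plus
candidate sources) and a "right" set of reference populations
differentially related to the left set, together with the block-jackknife
covariance of vec(X).  If the left populations descend from r ancestry
streams (as seen by the right set), E[X] has matrix rank at most r - 1.

* The rank test (qpWave-style) compares the generalized-least-squares fit
  of a rank-r mean to the saturated fit; twice the log-likelihood gap is
  chi-squared with (|left|-1-r)(|right|-1-r) degrees of freedom.
  Cladality of two left populations is rank 0 of their 1 x (m-1) system.
* Admixture proportions (qpAdm-style) come from the left null vector of
  the rank-(k-1) fitted mean for a target plus k sources: weights w with
  w' X ~ 0 and sum(w) = 1 express the target as a mixture of the sources.
  Negative weights are reported as-is; the plausibility classifier (model
  p-value and weight +- 2 SE inside [0, 1]) is the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .fstats import block_jackknife_cov
from .genio import BlockPartition, FreqTable

__all__ = ["F4System", "RankTestResult", "AdmixModel", "build_f4_system",
           "rank_test", "fit_qpadm", "classify_model", "sweep_models",
           "DEFAULT_RIGHT_SET"]

# The 11 reference populations used as the default right set: an African
# outgroup, diverse Middle Easterners, Caucasians, Oceanians, diverse
# Siberians, Native Americans and diverse Europeans.
DEFAULT_RIGHT_SET = [
    "Mbuti", "Palestinian", "Iranian", "Armenian", "Papuan",
    "Nganasan", "Ket", "Koryak", "Karitiana", "Irish", "Sardinian",
]


@dataclass
class F4System:
    """The left/right f4 matrix with its jackknife covariance."""

    left: list[str]    # first entry is the base l0 (the target in qpAdm)
    right: list[str]   # first entry is the base r0
    X: np.ndarray      # (|left|-1) x (|right|-1)
    cov: np.ndarray    # covariance of vec(X) (column-major/Fortran order)
    block_X: np.ndarray   # g x (|left|-1) x (|right|-1) per-block sums
    block_counts: np.ndarray
    n_blocks: int
    n_snps: int
    cov_reg: float = 1e-4

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def regularized_cov(self) -> np.ndarray:
        Q = self.cov
        return Q + self.cov_reg * float(np.mean(np.diag(Q))) * np.eye(Q.shape[0])


@dataclass
class RankTestResult:
    rank_tested: int
    chi2: float
    dof: int
    p_value: float
    n_iter: int = 0


@dataclass
class AdmixModel:
    """A fitted source decomposition of one target population."""

    target: str
    sources: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    p_value: float
    plausible: bool = False
    failure_reasons: list[str] = field(default_factory=list)

    def classify(self, p_cutoff: float = 0.05) -> "AdmixModel":
        return classify_model(self, p_cutoff)


class RankFitError(RuntimeError):
    def __init__(self, msg, ll_trace=None):
        super().__init__(msg)
        self.ll_trace = ll_trace or []


def build_f4_system(F: FreqTable, left: list[str], right: list[str],
                    blocks: BlockPartition, cov_reg: float = 1e-4) -> F4System:
    """f4(l0, l_i; r0, r_j) matrix on the complete-case SNPs of left+right."""
    if set(left) & set(right):
        raise ValueError(f"left and right overlap: {sorted(set(left) & set(right))}")
    if len(left) < 2:
        raise ValueError("need at least 2 left populations")
    if len(right) < len(left) + 1:
        raise ValueError("need |right| >= |left| + 1 for a testable system")
    pops = list(left) + list(right)
    idx = F.index_of(pops)
    mask = (F.total[idx] > 0).all(axis=0)
    if mask.sum() == 0:
        raise ValueError("no SNPs defined in every left and right population")
    p = F.freq[idx][:, mask]
    nl, nr = len(left), len(right)
    dl = p[1:nl] - p[0]            # (nl-1) x S : l0 - l_i sign absorbed below
    dr = p[nl + 1:] - p[nl]        # (nr-1) x S
    # f4(l0, l_i; r0, r_j) = E (p_l0 - p_li)(p_r0 - p_rj) = E dl_i * dr_j
    bid = blocks.block_of[mask]
    uniq, dense = np.unique(bid, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ValueError("need >= 2 non-empty jackknife blocks")
    counts = np.bincount(dense, minlength=g).astype(float)
    a, b = nl - 1, nr - 1
    block_X = np.zeros((g, a, b))
    for blk in range(g):
        sel = dense == blk
        block_X[blk] = dl[:, sel] @ dr[:, sel].T
    est = block_X.reshape(g, a * b, order="F") / counts[:, None]
    mean, cov = block_jackknife_cov(est, counts)
    X = mean.reshape(a, b, order="F")
    return F4System(list(left), list(right), X, cov, block_X, counts,
                    g, int(counts.sum()), cov_reg)


# ---------------------------------------------------------------------------
# rank-constrained GLS

def _gls_rank_fit(X: np.ndarray, Qinv: np.ndarray, r: int, tol: float = 1e-6,
                  max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Minimize (vec(X)-vec(AB'))' Qinv (vec(X)-vec(AB')) over A (a x r), B (b x r).

    Alternating generalized least squares; vec is column-major.  Returns
    (A, B, qform, iterations).
    """
    a, b = X.shape
    x = X.ravel(order="F")
    if r == 0:
        return np.zeros((a, 0)), np.zeros((b, 0)), float(x @ Qinv @ x), 0
    U, s, Vt = np.linalg.svd(X)
    A = U[:, :r] * s[:r]
    B = Vt[:r].T
    Ia = np.eye(a)
    prev = np.inf
    trace = []
    for it in range(1, max_iter + 1):
        # solve for A given B: vec(AB') = (B kron I_a) vec(A)
        G = np.kron(B, Ia)
        GtQ = G.T @ Qinv
        A = np.linalg.solve(GtQ @ G, GtQ @ x).reshape(a, r, order="F")
        # solve for B given A: vec(AB')[i + a j] = sum_k A[i,k] B[j,k]
        M = np.zeros((a * b, b * r))
        for k in range(r):
            for j in range(b):
                M[j * a:(j + 1) * a, k * b + j] = A[:, k]
        MtQ = M.T @ Qinv
        B = np.linalg.solve(MtQ @ M, MtQ @ x).reshape(b, r, order="F")
        d = x - (A @ B.T).ravel(order="F")
        qform = float(d @ Qinv @ d)
        trace.append(qform)
        if prev - qform < tol and it > 1:
            return A, B, qform, it
        prev = qform
    raise RankFitError(f"rank-{r} GLS fit did not converge in {max_iter} iterations",
                       ll_trace=trace)


def rank_test(S: F4System, r: int) -> RankTestResult:
    """Test whether E[X] has rank <= r (r+1 ancestry streams on the left)."""
    a, b = S.shape
    if not 0 <= r < min(a, b):
        raise ValueError(f"rank {r} not testable for a {a}x{b} system")
    Qinv = np.linalg.inv(S.regularized_cov())
    _, _, chi2, it = _gls_rank_fit(S.X, Qinv, r)
    dof = (a - r) * (b - r)
    p = float(scipy.stats.chi2.sf(chi2, dof))
    return RankTestResult(r, float(chi2), dof, p, it)


def _weights_from_system(X: np.ndarray, Qinv: np.ndarray) -> np.ndarray:
    """Mixture weights: left null vector of the rank-(k-1) fitted mean,
    normalized to sum to 1 (single source: exactly 1)."""
    k = X.shape[0]
    if k == 1:
        return np.ones(1)
    A, B, _, _ = _gls_rank_fit(X, Qinv, k - 1)
    # w' (A B') = 0  <=>  w' A = 0
    _, _, Vt = np.linalg.svd(A.T, full_matrices=True)
    w = Vt[-1]
    s = w.sum()
    if abs(s) < 1e-12:
        raise RankFitError("degenerate null vector: weights do not normalize")
    return w / s


def fit_qpadm(S: F4System, cov_reg: float | None = None) -> AdmixModel:
    """Admixture weights for left = [target, sources...] against the right set.

    Weights solve w' X = 0 (in the rank-(k-1) GLS sense) with sum 1; the
    model p-value is the rank-(k-1) test; SEs are delete-one-block
    jackknife re-fits of the full factorization.
    """
    k = S.shape[0]
    if not 1 <= k <= 3:
        raise ValueError("qpAdm supports 1-3 sources")
    if cov_reg is not None:
        S.cov_reg = cov_reg
    try:
        Qinv = np.linalg.inv(S.regularized_cov())
    except np.linalg.LinAlgError as exc:
        raise RankFitError("singular regularized covariance; increase cov_reg") from exc
    w = _weights_from_system(S.X, Qinv)
    p = rank_test(S, k - 1).p_value if k - 1 < min(S.shape) else float("nan")
    # delete-one-block re-fits
    g = S.n_blocks
    tot = S.block_X.sum(axis=0)
    n = S.block_counts.sum()
    w_loo = np.empty((g, k))
    for j in range(g):
        Xj = (tot - S.block_X[j]) / (n - S.block_counts[j])
        w_loo[j] = _weights_from_system(Xj, Qinv)
    m = S.block_counts
    h = n / m
    theta_bc = g * w - ((1.0 - m / n)[:, None] * w_loo).sum(axis=0)
    tau = h[:, None] * w[None, :] - (h - 1.0)[:, None] * w_loo
    var = (np.square(tau - theta_bc[None, :]) / (h - 1.0)[:, None]).sum(axis=0) / g
    se = np.sqrt(np.maximum(var, 0.0))
    if k == 1:
        se = np.zeros(1)
    model = AdmixModel(S.left[0], list(S.left[1:]), w, se, p)
    return classify_model(model)


def classify_model(M: AdmixModel, p_cutoff: float = 0.05) -> AdmixModel:
    """Plausibility: p >= cutoff and every weight +- 2 SE inside [0, 1]."""
    reasons = []
    if not M.p_value >= p_cutoff:
        reasons.append("p_below_cutoff")
    lo = M.weights - 2.0 * M.weight_se
    hi = M.weights + 2.0 * M.weight_se
    if (lo < 0.0).any() or (hi > 1.0).any():
        reasons.append("weight_ci_outside_unit")
    M.failure_reasons = reasons
    M.plausible = not reasons
    return M


# ---------------------------------------------------------------------------
# surrogate sweeps

def sweep_models(F: FreqTable, target: str, esea: list[str], nega: str,
                 sas: list[str], right: list[str], blocks: BlockPartition,
                 p_cutoff: float = 0.05, cov_reg: float = 1e-4) -> pd.DataFrame:
    """Cladality, 2-way and 3-way admixture models over surrogate sweeps.

    Per East/Southeast Asian surrogate E: the rank-0 cladality test of
    {target, E}; the 2-way model target = E + nega; and one 3-way model
    target = E + nega + S per deep-ancestry surrogate S.  Rows mirror a
    model table: one line per model with weights, SEs, p and the verdict.
    """
    for lab, pops in (("esea", esea), ("nega", [nega]), ("sas", sas)):
        clash = set(pops) & set(right)
        if clash:
            raise ValueError(f"{lab} surrogates overlap the right set: {sorted(clash)}")
    rows = []

    def emit(model_kind, sources):
        S = build_f4_system(F, [target] + sources, right, blocks, cov_reg)
        if len(sources) == 1:
            p = rank_test(S, 0).p_value
            m = AdmixModel(target, sources, np.ones(1), np.zeros(1), p)
            classify_model(m, p_cutoff)
        else:
            m = fit_qpadm(S)
            classify_model(m, p_cutoff)
        rows.append({
            "target": target, "model": model_kind,
            "sources": ";".join(sources),
            "weights": ";".join(f"{w:.4f}" for w in m.weights),
            "weight_se": ";".join(f"{s:.4f}" for s in m.weight_se),
            "p_value": m.p_value, "plausible": m.plausible,
            "failure_reasons": ";".join(m.failure_reasons),
            "n_snps": S.n_snps,
            "_weights": m.weights, "_se": m.weight_se, "_sources": sources,
        })

    for e in esea:
        emit("cladality", [e])
        emit("2way", [e, nega])
        for s in sas:
            emit("3way", [e, nega, s])
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean weight per ancestry role across plausible models of each kind."""
    out = []
    for kind in ("2way", "3way"):
        sub = table[(table["model"] == kind) & table["plausible"]]
        if not len(sub):
            continue
        k = 2 if kind == "2way" else 3
        W = np.stack([w for w in sub["_weights"]])
        roles = ["esea", "nega", "sas"][:k]
        out.append({"model": kind, "n_plausible": len(sub),
                    **{f"mean_w_{r}": W[:, i].mean() for i, r in enumerate(roles)}})
    return pd.DataFrame(out)
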