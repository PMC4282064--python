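"""Permutation and resampling inference for dyadic and node-based data.

Matrix tests (QAP, MRQAP) permute node identities — rows and columns of one
matrix jointly — so the null distribution respects the row/column dependence
of dyadic data.  Node-metric tests permute node labels, stratified by colony
when metrics are normalised within colonies.  All p-values use the add-one
convention p = (#as-or-more-extreme + 1)/(n_perm + 1) and are exactly
reproducible from the recorded seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PermTestResult",
    "qap_correlation",
    "mrqap_dsp",
    "MrqapResult",
    "node_label_test",
    "spearman_perm",
    "wilcoxon_signed_rank",
    "chisq_gof",
    "one_sample_t",
]

_EPS = 1e-12


@dataclass
class PermTestResult:
    statistic_name: str
    observed: float
    n_perm: int
    p_value: float
    tail: str = "two"
    seed: int | None = None
    n: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "tail": self.tail,
            "seed": self.seed,
            "n": self.n,
        }
        d.update(self.extra)
        return d


def _perm_pvalue(observed: float, null: np.ndarray, tail: str) -> float:
    if tail == "two":
        extreme = np.abs(null) >= abs(observed) - _EPS
    elif tail == "greater":
        extreme = null >= observed - _EPS
    elif tail == "less":
        extreme = null <= observed + _EPS
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((extreme.sum() + 1) / (len(null) + 1))


def _offdiag_vector(m: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu], iu


def qap_correlation(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 5_000,
    seed: int | None = None,
    tail: str = "two",
) -> PermTestResult:
    """Quadratic Assignment Procedure correlation between two dyadic matrices.

    Pearson R over the off-diagonal cells; the null distribution permutes
    node identities (joint row/column shuffles) of the second matrix.
    Matrices must share node order; diagonals are ignored.
    """
    x, iu = _offdiag_vector(m1)
    m2 = np.asarray(m2, dtype=float)
    y, _ = _offdiag_vector(m2)
    if m2.shape != np.asarray(m1).shape:
        raise ValueError("matrices must have identical shape")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("QAP requires complete matrices; impute or drop NaN dyads first")
    if x.std() < _EPS or y.std() < _EPS:
        raise ValueError("QAP undefined: a matrix has zero off-diagonal variance")
    n = m1.shape[0]
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)
    yc = y - y.mean()
    observed = float(xn @ (yc / np.linalg.norm(yc)))
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    vals = m2[perms[:, iu[0]], perms[:, iu[1]]]
    vals -= vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vals, axis=1)
    norms[norms < _EPS] = np.nan
    null = (vals @ xn) / norms
    null = null[~np.isnan(null)]
    return PermTestResult(
        "QAP Pearson R", observed, n_perm, _perm_pvalue(observed, null, tail),
        tail=tail, seed=seed, n=n,
    )


@dataclass
class MrqapResult:
    names: list[str]
    betas: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int | None
    n: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "predictors": self.names,
            "betas": [float(b) for b in self.betas],
            "p_values": [float(p) for p in self.p_values],
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n": self.n,
            "r_squared": self.r_squared,
        }


def mrqap_dsp(
    y: np.ndarray,
    xs: list[np.ndarray],
    n_perm: int = 2_000,
    seed: int | None = None,
    names: list[str] | None = None,
    tail: str = "two",
) -> MrqapResult:
    """Multiple-regression QAP with Dekker double-semi-partialing inference.

    OLS of the vectorised response dyads on the vectorised predictor dyads
    (intercept included).  For each predictor, its matrix is residualised on
    the remaining predictors, the residual matrix is permuted by joint
    row/column shuffles, and the coefficient recomputed — permuting only the
    unique part of each predictor guards the test against collinearity
    between predictors.
    """
    yv, iu = _offdiag_vector(y)
    n = np.asarray(y).shape[0]
    if not xs:
        raise ValueError("need at least one predictor matrix")
    xvs = []
    for x in xs:
        xv, _ = _offdiag_vector(x)
        if np.asarray(x).shape != np.asarray(y).shape:
            raise ValueError("all matrices must share the response's shape")
        xvs.append(xv)
    names = names or [f"x{i + 1}" for i in range(len(xvs))]
    if yv.std() < _EPS:
        raise ValueError("response matrix has zero off-diagonal variance")
    X = np.column_stack([np.ones_like(yv)] + xvs)
    # exact-collinearity check, naming the offending pair
    for i in range(len(xvs)):
        for j in range(i + 1, len(xvs)):
            a = xvs[i] - xvs[i].mean()
            b = xvs[j] - xvs[j].mean()
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na < _EPS or nb < _EPS or abs(a @ b / (na * nb)) > 1 - 1e-10:
                raise ValueError(
                    f"predictors {names[i]!r} and {names[j]!r} are collinear (or constant)"
                )
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    fitted = X @ beta
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rng = np.random.default_rng(seed)
    p_values = np.empty(len(xvs))
    for j, xv in enumerate(xvs):
        others = np.column_stack(
            [np.ones_like(yv)] + [xvs[k] for k in range(len(xvs)) if k != j]
        )
        q, _ = np.linalg.qr(others)
        e = xv - q @ (q.T @ xv)  # predictor residualised on the others
        ry = yv - q @ (q.T @ yv)
        emat = np.zeros((n, n))
        emat[iu] = e
        emat += emat.T
        obs_beta = float((ry @ e) / (e @ e))
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        pe = emat[perms[:, iu[0]], perms[:, iu[1]]]
        pe_res = pe - (pe @ q) @ q.T
        denom = (pe_res * pe_res).sum(axis=1)
        denom[denom < _EPS] = np.nan
        null = (pe_res @ ry) / denom
        null = null[~np.isnan(null)]
        p_values[j] = _perm_pvalue(obs_beta, null, tail)
    return MrqapResult(names, beta[1:], p_values, n_perm, seed, n, r2)


def node_label_test(
    values,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
    strata=None,
    tail: str = "two",
    statistic_name: str = "mean difference (label 1 - label 0)",
) -> PermTestResult:
    """Monte Carlo node-label test for a node metric between two classes.

    Observed statistic: mean(values | label 1) - mean(values | label 0).
    The null shuffles labels across nodes, within strata when given (use the
    colony as stratum for metrics normalised per colony).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    strata_arr = None if strata is None else np.asarray(strata)[keep]
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be non-empty")
    if n1 == 1 or n0 == 1:
        warnings.warn("a label class has a single member; p-value resolution is limited",
                      stacklevel=2)
    observed = float(values[labels == 1].mean() - values[labels == 0].mean())
    rng = np.random.default_rng(seed)
    lab_mat = np.tile(labels, (n_perm, 1))
    if strata_arr is None:
        lab_mat = rng.permuted(lab_mat, axis=1)
    else:
        for s in np.unique(strata_arr):
            idx = np.flatnonzero(strata_arr == s)
            lab_mat[:, idx] = rng.permuted(lab_mat[:, idx], axis=1)
    sums1 = lab_mat @ values
    counts1 = lab_mat.sum(axis=1)
    total = values.sum()
    null = sums1 / counts1 - (total - sums1) / (len(values) - counts1)
    return PermTestResult(
        statistic_name, observed, n_perm, _perm_pvalue(observed, null, tail),
        tail=tail, seed=seed, n=len(values),
        extra={"n_label1": n1, "n_label0": n0, "stratified": strata is not None},
    )


def spearman_perm(
    x, y, n_perm: int = 10_000, seed: int | None = None, tail: str = "two"
) -> PermTestResult:
    """Spearman rank correlation with a pair-shuffling permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("Spearman test needs at least 3 pairs")
    if x.std() < _EPS or y.std() < _EPS:
        raise ValueError("Spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    rxn = rxc / np.linalg.norm(rxc)
    ryc = ry - ry.mean()
    ryn = ryc / np.linalg.norm(ryc)
    observed = float(rxn @ ryn)
    rng = np.random.default_rng(seed)
    perm = np.tile(ryn, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    null = perm @ rxn
    return PermTestResult(
        "Spearman Rs", observed, n_perm, _perm_pvalue(observed, null, tail),
        tail=tail, seed=seed, n=len(x),
    )


def _exact_signed_rank_tail(doubled_ranks: np.ndarray, v_doubled: int) -> tuple[float, float]:
    """P(T+ >= v) and P(T+ <= v) for the exact signed-rank null.

    Ranks arrive doubled so average-rank ties are integers; the distribution
    of the doubled positive-rank sum is built by polynomial convolution over
    sign assignments (each of the 2^n sign vectors equally likely).
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for t in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[t:] = dist[: total + 1 - t]
        dist = 0.5 * (dist + shifted)
    v = int(round(v_doubled))
    return float(dist[v:].sum()), float(dist[: v + 1].sum())


def wilcoxon_signed_rank(
    values, mu: float = 0.0, alternative: str = "two-sided"
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of location against mu.

    Returns (V, p) with V the sum of the ranks of positive differences.
    Zero differences are dropped; ties get average ranks.  The null
    distribution is exact (full sign enumeration by convolution) for
    n <= 25 retained differences, and a tie-corrected normal approximation
    with continuity correction beyond that.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal mu; signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= 25:
        doubled = np.round(2 * ranks).astype(int)
        p_ge, p_le = _exact_signed_rank_tail(doubled, int(round(2 * v)))
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_ge, p_le))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        sd = np.sqrt(var)
        if alternative == "greater":
            p = float(stats.norm.sf((v - 0.5 - mean) / sd))
        elif alternative == "less":
            p = float(stats.norm.cdf((v + 0.5 - mean) / sd))
        else:
            z = (v - mean - np.sign(v - mean) * 0.5) / sd
            p = float(2 * stats.norm.sf(abs(z)))
            p = min(1.0, p)
    return v, p


def chisq_gof(observed, expected_props) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit of counts against proportions."""
    observed = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if observed.shape != props.shape:
        raise ValueError("observed counts and expected proportions differ in length")
    expected = props / props.sum() * observed.sum()
    if (expected < 1).any():
        raise ValueError("expected counts below 1; chi-square invalid")
    if (expected < 5).any():
        warnings.warn("expected counts below 5; chi-square approximation is rough",
                      stacklevel=2)
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return float(chi2), len(observed) - 1, float(p)


def one_sample_t(values, popmean: float = 0.0) -> dict:
    """One-sample t-test helper used to pool per-colony statistics against 0."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        raise ValueError("need at least 2 values for a one-sample t-test")
    t, p = stats.ttest_1samp(values, popmean)
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "t": float(t),
        "df": len(values) - 1,
        "p_value": float(p),
        "n": len(values),
    }
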