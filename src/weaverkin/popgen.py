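"""Allele frequencies, locus QC, and Queller–Goodnight pairwise relatedness.

The relatedness estimator is the moment estimator of Queller & Goodnight for
codominant markers, in the ratio-of-sums form: per-locus numerator and
denominator contributions are summed over all shared loci and over both dyad
directions before the final division.  This is the convention of the kinship
software used in field studies of this kind and is markedly more stable than
averaging per-locus ratios when only a modest number of microsatellites is
available.

Reference allele frequencies are computed over the whole genotyped
population (all colonies pooled), including the focal dyad — appropriate
when colonies are open, dispersal mixes alleles across the population, and
single colonies are far too small to serve as their own reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "LocusQC",
    "RelatednessMatrix",
    "allele_frequencies",
    "heterozygosity",
    "hwe_test",
    "null_allele_frequency",
    "ld_test",
    "bh_fdr",
    "locus_qc",
    "qg_relatedness",
    "relatedness_matrix",
]


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies over all non-missing diploid calls."""

    loci: list[str]
    freqs: list[np.ndarray]  # per locus, frequency of allele code k
    n_typed: np.ndarray  # individuals successfully typed per locus

    def as_dict(self, table: GenotypeTable) -> dict[str, dict[str, float]]:
        return {
            locus: {
                table.allele_labels[j][k]: float(p)
                for k, p in enumerate(self.freqs[j])
                if p > 0
            }
            for j, locus in enumerate(self.loci)
        }


def allele_frequencies(g: GenotypeTable) -> AlleleFrequencies:
    """Count-based allele frequencies per locus; errors on untyped loci."""
    freqs: list[np.ndarray] = []
    n_typed = np.zeros(g.n_loci, dtype=int)
    for j, locus in enumerate(g.loci):
        codes = g.codes[:, j, :]
        typed = codes[:, 0] >= 0
        n_typed[j] = int(typed.sum())
        if n_typed[j] == 0:
            raise ValueError(f"locus {locus!r}: no typed individuals")
        counts = np.bincount(codes[typed].ravel(), minlength=len(g.allele_labels[j]))
        freqs.append(counts / counts.sum())
    return AlleleFrequencies(list(g.loci), freqs, n_typed)


def heterozygosity(g: GenotypeTable, freqs: AlleleFrequencies) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per locus.

    He uses the small-sample correction 2n/(2n-1) * (1 - sum p_k^2), with n
    the number of typed individuals at the locus.
    """
    rows = []
    for j, locus in enumerate(g.loci):
        codes = g.codes[:, j, :]
        typed = codes[:, 0] >= 0
        n = int(typed.sum())
        ho = float((codes[typed, 0] != codes[typed, 1]).mean()) if n else np.nan
        p = freqs.freqs[j]
        he = 2 * n / (2 * n - 1) * (1.0 - float(p @ p)) if n > 0 and 2 * n > 1 else 0.0
        rows.append((locus, n, ho, he))
    return pd.DataFrame(rows, columns=["locus", "n_typed", "Ho", "He"]).set_index("locus")


def hwe_test(
    g: GenotypeTable, locus: str, reps: int = 10_000, seed: int | None = None
) -> float:
    """Monte Carlo exact test of Hardy–Weinberg equilibrium at one locus.

    The 2n observed alleles are shuffled among individuals and the
    heterozygote count recomputed; the p-value is the add-one-corrected
    fraction of shuffles whose heterozygote count deviates from the
    permutation mean at least as much as the observed count (two-sided).
    """
    j = g.loci.index(locus)
    codes = g.codes[:, j, :]
    typed = codes[codes[:, 0] >= 0]
    n = len(typed)
    if n < 20:
        warnings.warn(f"locus {locus!r}: only {n} typed individuals; HWE test is weak",
                      stacklevel=2)
    alleles = typed.ravel()
    if len(np.unique(alleles)) < 2:
        warnings.warn(f"locus {locus!r} is monomorphic; HWE p-value set to 1", stacklevel=2)
        return 1.0
    obs_het = int((typed[:, 0] != typed[:, 1]).sum())
    rng = np.random.default_rng(seed)
    perm_het = np.empty(reps, dtype=int)
    pool = alleles.copy()
    for r in range(reps):
        rng.shuffle(pool)
        perm_het[r] = int((pool[0::2] != pool[1::2]).sum())
    center = perm_het.mean()
    extreme = np.abs(perm_het - center) >= abs(obs_het - center) - 1e-12
    return float((extreme.sum() + 1) / (reps + 1))


def null_allele_frequency(ho: float, he: float) -> float:
    """Chakraborty-style null allele frequency estimate (He-Ho)/(He+Ho)."""
    if he <= 0:
        return 0.0
    return float((he - ho) / (he + ho))


def _genotype_labels(codes: np.ndarray) -> np.ndarray:
    """Unordered genotype label per individual (codes: (n, 2), typed only)."""
    lo = np.minimum(codes[:, 0], codes[:, 1])
    hi = np.maximum(codes[:, 0], codes[:, 1])
    return lo * (hi.max() + 1) + hi


def _g_statistic(cells: np.ndarray, expected: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cells > 0, cells * np.log(cells / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_test(
    g: GenotypeTable,
    locus_a: str,
    locus_b: str,
    reps: int = 2_000,
    seed: int | None = None,
) -> float:
    """Permutation test of genotypic association between two loci.

    The statistic is the G statistic of the two-locus genotype contingency
    table; the null distribution shuffles one locus's genotypes across the
    mutually typed individuals.
    """
    ja, jb = g.loci.index(locus_a), g.loci.index(locus_b)
    mask = (g.codes[:, ja, 0] >= 0) & (g.codes[:, jb, 0] >= 0)
    n = int(mask.sum())
    if n < 20:
        warnings.warn(
            f"loci {locus_a!r}/{locus_b!r}: only {n} mutually typed individuals",
            stacklevel=2,
        )
    a = _genotype_labels(g.codes[mask][:, ja, :])
    b = _genotype_labels(g.codes[mask][:, jb, :])
    _, a = np.unique(a, return_inverse=True)
    _, b = np.unique(b, return_inverse=True)
    ka, kb = a.max() + 1, b.max() + 1
    if ka < 2 or kb < 2:
        return 1.0
    # margins are invariant under permutation, so the expected table is fixed
    ra = np.bincount(a, minlength=ka).astype(float)
    rb = np.bincount(b, minlength=kb).astype(float)
    expected = np.outer(ra, rb) / n
    counts = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb).astype(float)
    obs = _g_statistic(counts, expected)
    rng = np.random.default_rng(seed)
    count = 0
    bp = b.copy()
    for _ in range(reps):
        rng.shuffle(bp)
        cells = np.bincount(a * kb + bp, minlength=ka * kb).reshape(ka, kb).astype(float)
        if _g_statistic(cells, expected) >= obs - 1e-12:
            count += 1
    return float((count + 1) / (reps + 1))


def bh_fdr(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: boolean rejection flags at level alpha."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = np.flatnonzero(below).max()
        flags[order[: k + 1]] = True
    return flags


def locus_qc(
    g: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    hwe_reps: int = 2_000,
    ld_reps: int = 500,
    fdr_alpha: float = 0.05,
    seed: int | None = None,
) -> "LocusQC":
    """Full marker QC: allele counts, Ho/He, HWE, null alleles, pairwise LD."""
    if freqs is None:
        freqs = allele_frequencies(g)
    het = heterozygosity(g, freqs)
    rng = np.random.default_rng(seed)
    rows = []
    for j, locus in enumerate(g.loci):
        ho, he = het.loc[locus, "Ho"], het.loc[locus, "He"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hwe_p = hwe_test(g, locus, reps=hwe_reps, seed=int(rng.integers(2**31)))
        rows.append(
            (
                locus,
                int((freqs.freqs[j] > 0).sum()),
                int(het.loc[locus, "n_typed"]),
                ho,
                he,
                hwe_p,
                null_allele_frequency(ho, he),
            )
        )
    per_locus = pd.DataFrame(
        rows, columns=["locus", "n_alleles", "n_typed", "Ho", "He", "hwe_p", "null_freq"]
    ).set_index("locus")
    pair_rows = []
    for i in range(g.n_loci):
        for j in range(i + 1, g.n_loci):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = ld_test(g, g.loci[i], g.loci[j], reps=ld_reps,
                            seed=int(rng.integers(2**31)))
            pair_rows.append((g.loci[i], g.loci[j], p))
    ld = pd.DataFrame(pair_rows, columns=["locus_a", "locus_b", "ld_p"])
    if len(ld):
        ld["fdr_flag"] = bh_fdr(ld["ld_p"].to_numpy(), alpha=fdr_alpha)
    else:
        ld["fdr_flag"] = pd.Series(dtype=bool)
    return LocusQC(per_locus=per_locus, ld_pairs=ld)


@dataclass
class LocusQC:
    per_locus: pd.DataFrame
    ld_pairs: pd.DataFrame


# ---------------------------------------------------------------------------
# Queller–Goodnight relatedness


def _pair_terms(
    cx: np.ndarray, cy: np.ndarray, p: np.ndarray
) -> tuple[float, float]:
    """One-directional numerator/denominator sums for a single locus.

    ``cx``/``cy`` are the two allele codes of x and y; ``p`` is the reference
    frequency vector.  The focal individual is x: for each of x's two allele
    positions a, the numerator accrues (share of a within y's genotype -
    p_a) and the denominator (share of a within x's own genotype - p_a).
    """
    num = den = 0.0
    for a in cx:
        share_y = 0.5 * (float(cy[0] == a) + float(cy[1] == a))
        share_x = 0.5 * (float(cx[0] == a) + float(cx[1] == a))
        num += share_y - p[a]
        den += share_x - p[a]
    return num, den


def qg_relatedness(
    g: GenotypeTable, freqs: AlleleFrequencies, dyad: tuple[str, str]
) -> float:
    """Pairwise Queller–Goodnight relatedness for one dyad.

    Symmetrised ratio-of-sums: numerators and denominators are pooled over
    both directions (x focal, then y focal) and over all mutually typed loci
    before dividing.  Returns NaN (with a warning) when the dyad shares no
    typed locus or the pooled denominator vanishes.
    """
    ix = g.ids.index(dyad[0])
    iy = g.ids.index(dyad[1])
    num = den = 0.0
    shared = 0
    for j in range(g.n_loci):
        cx, cy = g.codes[ix, j], g.codes[iy, j]
        if cx[0] < 0 or cy[0] < 0:
            continue
        shared += 1
        p = freqs.freqs[j]
        n1, d1 = _pair_terms(cx, cy, p)
        n2, d2 = _pair_terms(cy, cx, p)
        num += n1 + n2
        den += d1 + d2
    if shared == 0:
        warnings.warn(f"dyad {dyad}: no mutually typed loci", stacklevel=2)
        return float("nan")
    if abs(den) < 1e-12:
        warnings.warn(f"dyad {dyad}: zero pooled denominator", stacklevel=2)
        return float("nan")
    return num / den


@dataclass
class RelatednessMatrix:
    """Symmetric matrix of pairwise relatedness estimates.

    The diagonal is fixed at 1 by convention and excluded from every summary
    statistic.  Values are not clipped: the moment estimator legitimately
    strays outside [-1, 1] for individual dyads.
    """

    ids: list[str]
    values: np.ndarray
    reference: str = "population"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix shape mismatch")
        self._index = {b: i for i, b in enumerate(self.ids)}

    def r(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids) -> "RelatednessMatrix":
        idx = [self._index[b] for b in ids]
        return RelatednessMatrix(list(ids), self.values[np.ix_(idx, idx)], self.reference)

    def offdiag(self, ids=None) -> np.ndarray:
        """Upper-triangle dyadic values for an id subset (default: all)."""
        m = self.values if ids is None else self.submatrix(list(ids)).values
        iu = np.triu_indices(len(m), k=1)
        return m[iu]

    def subset_stats(self, ids=None) -> tuple[float, float]:
        """Mean and SD of off-diagonal relatedness over an id subset."""
        vals = self.offdiag(ids)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def to_long_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.ids), k=1)
        return pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu[0]],
                "id2": [self.ids[j] for j in iu[1]],
                "r": self.values[iu],
            }
        )


def relatedness_matrix(
    g: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    ids=None,
    reference: str = "population",
) -> RelatednessMatrix:
    """All-dyads Queller–Goodnight relatedness, fully vectorised.

    For each locus the per-dyad numerator/denominator contributions of both
    directions are accumulated with boolean allele-sharing comparisons over
    the full individual x individual grid; the final estimate divides the
    pooled sums.  Dyads with no mutually typed loci or a vanishing pooled
    denominator come out NaN.  The diagonal is set to 1 by convention.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    sub = g if ids is None else g.subset(list(ids))
    n = sub.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int32)
    for j in range(sub.n_loci):
        codes = sub.codes[:, j, :]
        typed = codes[:, 0] >= 0
        p = freqs.freqs[j]
        a0 = codes[:, 0].copy()
        a1 = codes[:, 1].copy()
        a0[~typed] = 0  # placeholder; masked out below
        a1[~typed] = 0
        pa = p[a0] + p[a1]  # sum of reference freqs of x's two alleles
        # share of x's allele at position s within y's genotype, for all (x, y)
        # (cast before adding: numpy bool-array addition is logical OR)
        s0 = 0.5 * ((a0[:, None] == a0[None, :]).astype(np.float64)
                    + (a0[:, None] == a1[None, :]))
        s1 = 0.5 * ((a1[:, None] == a0[None, :]).astype(np.float64)
                    + (a1[:, None] == a1[None, :]))
        share_in = s0 + s1  # rows: focal x; cols: partner y
        own = np.diagonal(share_in).copy()  # share of x's alleles in x itself
        both = typed[:, None] & typed[None, :]
        d_num = np.where(both, share_in - pa[:, None], 0.0)
        d_den = np.where(both, (own - pa)[:, None], 0.0)
        num += d_num
        den += d_den
        shared += both
    num_t = num + num.T
    den_t = den + den.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num_t / den_t
    r[shared == 0] = np.nan
    r[np.abs(den_t) < 1e-12] = np.nan
    np.fill_diagonal(r, 1.0)
    return RelatednessMatrix(list(sub.ids), r, reference=reference)
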