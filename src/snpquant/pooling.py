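"""Pooled-DNA allele frequencies and family contribution deconvolution.

A pooled assay yields one allelic proportion p per SNP for the whole pool.
Because per-SNP clusters are heterogeneous and off-centre, p is mapped to
an allele-frequency estimate f-hat through a piecewise-linear map anchored
at the calibrated cluster means: f = 0 at mu_AA, 0.5 at mu_AB, 1 at mu_BB,
linear in between and clipped outside.  Each estimate carries the Welch
statistic of the interval it fell in (tau_A below the heterozygote mean,
tau_B above) as a precision measure.

Family contributions to a pool are recovered from the linear model
y ~ X beta: rows are SNPs, columns families, X_jl the expected offspring
B-allele frequency of family l (mean of the parents' transmission
probabilities), y the pooled frequency estimates, weighted by the squared
Welch statistics.  The solution is a weighted non-negative least squares
fit, rescaled to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from snpquant.intensity import GenotypeStore, SnpParams, missing_parent_matrix
from snpquant.parentage import transmission_vector


def pooled_allele_frequency(p_pool: float, params: SnpParams) -> float:
    """Piecewise-linear B-allele frequency from a pooled allelic proportion.

    0 below the AA cluster mean, 1 above the BB mean, linear through 0.5 at
    the heterozygote mean in between.  NaN for missing input or an unusable
    SNP.
    """
    if not params.usable or not np.isfinite(p_pool):
        return float("nan")
    return float(
        np.interp(p_pool, [params.mu_aa, params.mu_ab, params.mu_bb], [0.0, 0.5, 1.0])
    )


def pool_weight(p_pool: float, params: SnpParams) -> float:
    """Welch statistic of the interval containing a pooled proportion.

    tau_A for p at or below the heterozygote cluster mean, tau_B above; the
    regression weight used downstream is tau squared.  A missing estimate
    gets weight 1.0.
    """
    if not params.usable or not np.isfinite(p_pool):
        return 1.0
    return params.tau_a if p_pool <= params.mu_ab else params.tau_b


def individual_based_pool_frequency(
    member_p: Sequence[float] | np.ndarray, params: SnpParams
) -> float:
    """Pool allele frequency from its members' individual proportions.

    The same piecewise map applied per member, averaged over members with a
    non-missing proportion; NaN when none have data.
    """
    p = np.asarray(member_p, float)
    ok = np.isfinite(p)
    if not params.usable or not ok.any():
        return float("nan")
    f = np.interp(p[ok], [params.mu_aa, params.mu_ab, params.mu_bb], [0.0, 0.5, 1.0])
    return float(f.mean())


def family_frequency_matrix(
    families: Sequence[tuple[str | None, str | None]],
    store: GenotypeStore,
    freqs: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Expected offspring B-allele frequency per (SNP, family).

    X_jl = (T_sire[B] + T_dam[B]) / 2 from the parents' genotype matrices;
    a missing parent — or a parent without a genotype at that SNP — uses
    the allele-frequency matrix F F', whose transmission vector is F
    itself.  Cells are NaN only if the frequency itself is unavailable.
    """
    n_snps = len(store.snps)
    X = np.full((n_snps, len(families)), np.nan)
    for l, (sire, dam) in enumerate(families):
        for j, snp in enumerate(store.snps):
            f = np.asarray(freqs[snp], float)
            tb = []
            for parent in (sire, dam):
                g = store.get(parent, snp) if parent is not None else None
                if g is None:
                    tb.append(f[1])
                else:
                    tb.append(transmission_vector(g)[1])
            X[j, l] = 0.5 * (tb[0] + tb[1])
    return X


@dataclass
class ContributionProblem:
    """Weighted least-squares problem for one pool's family contributions.

    Missing cells in X and y are pre-filled with 0.5 and missing weights
    with 1.0 so every SNP row stays in the design.
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    family_ids: list[str]


def build_contribution_problem(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    family_ids: Sequence[str] | None = None,
) -> ContributionProblem:
    """Assemble a :class:`ContributionProblem`, applying the missing-value fills."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    if w is None:
        w = np.ones_like(y)
    w = np.asarray(w, float).copy()
    if X.shape[0] != y.size or y.size != w.size:
        raise ValueError("X rows, y and w must align")
    X[np.isnan(X)] = 0.5
    y[np.isnan(y)] = 0.5
    w[~np.isfinite(w) | (w <= 0)] = 1.0
    if family_ids is None:
        family_ids = [f"family_{i}" for i in range(X.shape[1])]
    return ContributionProblem(X, y, w, list(family_ids))


@dataclass
class ContributionEstimate:
    """Family contribution estimates for one pool.

    ``beta_raw`` is the non-negative least squares solution; ``beta`` the
    rescaled contributions summing to one.  ``unidentifiable`` flags
    families whose design column is all zero.
    """

    beta_raw: np.ndarray
    beta: np.ndarray
    sum_raw: float
    family_ids: list[str]
    unidentifiable: list[str] = field(default_factory=list)


def estimate_contributions(problem: ContributionProblem) -> ContributionEstimate:
    """Weighted non-negative least squares family contributions.

    Solves min || sqrt(w) (X beta - y) ||^2 with beta >= 0 by scaling rows
    by sqrt(w) and calling a non-negative least squares solver, then
    rescales beta to sum to one.  The raw solution sum is reported — on
    well-posed pools it sits close to one before rescaling.
    """
    sw = np.sqrt(problem.w)
    A = problem.X * sw[:, None]
    b = problem.y * sw
    beta_raw, _ = nnls(A, b)
    total = float(beta_raw.sum())
    if total > 0:
        beta = beta_raw / total
    else:
        beta = np.full_like(beta_raw, 1.0 / beta_raw.size)
    unident = [
        fid
        for fid, col in zip(problem.family_ids, problem.X.T)
        if not np.any(col != 0.0)
    ]
    return ContributionEstimate(beta_raw, beta, total, list(problem.family_ids), unident)
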