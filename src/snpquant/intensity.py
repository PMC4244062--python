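"""Raw two-channel intensities to quantitative genotype matrices.

A biallelic SNP assay reports, per sample and SNP, an area for each allele
channel (``a1`` for allele A, ``a2`` for allele B) and an uncertainty for
each (``u1``, ``u2``).  The uncertainty-adjusted areas are mapped to a polar
*allelic proportion* ``p = atan2(a2-u2, a1-u1) / (pi/2)`` in [0, 1]: 0 is a
pure A signal, 1 a pure B signal.  Per SNP, the three genotype clusters
(AA, AB, BB) on the p axis are calibrated from platform genotype calls,
giving cluster means and standard deviations that are deliberately *not*
rescaled to (0, 0.5, 1) — real panels have heterogeneous, off-centre
clusters.

From the calibration, every assay yields a *quantitative genotype*: a 2x2
probability matrix over ordered allele pairs (paternal allele indexes rows,
maternal allele indexes columns), with entries proportional to the normal
density heights of the three clusters at the observed p (the heterozygote
height split equally between the two ordered cells).  Three further matrix
flavours support the classical methods: a discrete call matrix D, a
perturbed matrix M = (1-eps) D + eps F F' modelling genotyping error at
rate eps, and the allele-frequency outer product F F' standing in for a
missing parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

HALF_PI = math.pi / 2.0

GENOTYPE_CLASSES = ("AA", "AB", "BB")

#: default minimum clamped adjusted intensity for a usable individual assay
DEFAULT_MIN_INTENSITY = 3.0
#: default minimum per-class sample count for calibration
DEFAULT_MIN_CLASS_N = 3
#: floor applied to per-class standard deviations
DEFAULT_SIGMA_FLOOR = 1e-3
#: quantitative-certainty threshold for declaring a discrete genotype
DEFAULT_CALL_THRESHOLD = 0.98
#: floor for the assumed genotyping error rate
DEFAULT_ERROR_FLOOR = 0.01


@dataclass(frozen=True)
class AssayRecord:
    """One raw assay: a sample x SNP pair of channel areas and uncertainties."""

    sample_id: str
    snp_id: str
    a1: float
    u1: float
    a2: float
    u2: float
    platform_call: str | None = None

    def __post_init__(self) -> None:
        for name in ("a1", "u1", "a2", "u2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"assay ({self.sample_id}, {self.snp_id}): "
                    f"{name}={v!r} must be finite and non-negative"
                )
        if self.platform_call not in (None, "AA", "AB", "BB"):
            raise ValueError(f"unknown platform call {self.platform_call!r}")


@dataclass(frozen=True)
class AllelicProportion:
    """Polar-coordinate allelic proportion for one assay.

    ``p`` is NaN when the clamped adjusted intensity fell below the
    usability threshold; ``clamped`` records whether either channel was
    negative after uncertainty adjustment (a provenance flag, not an error).
    """

    sample_id: str
    snp_id: str
    p: float
    adjusted_intensity: float
    clamped: bool = False

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.p)


def compute_allelic_proportion(
    assay: AssayRecord,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
    inclusive_threshold: bool = False,
) -> AllelicProportion:
    """Map one assay to its allelic proportion.

    Adjusted channel signals ``a - u`` are clamped at zero before the polar
    transform, so p is guaranteed in [0, 1].  The assay is declared missing
    when the summed clamped signal is below ``min_intensity`` (strictly
    below for individual assays; at-or-below when ``inclusive_threshold`` is
    set, the failure rule used for pooled assays).
    """
    x = max(assay.a1 - assay.u1, 0.0)
    y = max(assay.a2 - assay.u2, 0.0)
    clamped = (assay.a1 - assay.u1 < 0.0) or (assay.a2 - assay.u2 < 0.0)
    intensity = x + y
    failed = intensity <= min_intensity if inclusive_threshold else intensity < min_intensity
    if failed or (x == 0.0 and y == 0.0):
        p = float("nan")
    else:
        p = math.atan2(y, x) / HALF_PI
    return AllelicProportion(assay.sample_id, assay.snp_id, p, intensity, clamped)


def allelic_proportions(
    assays: pd.DataFrame,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
    inclusive_threshold: bool = False,
) -> pd.DataFrame:
    """Vectorised :func:`compute_allelic_proportion` over an assay table.

    Expects columns ``sample_id, snp_id, a1, u1, a2, u2`` and optionally
    ``call``; returns the table with ``p`` and ``intensity`` columns added.
    """
    a1 = assays["a1"].to_numpy(float)
    u1 = assays["u1"].to_numpy(float)
    a2 = assays["a2"].to_numpy(float)
    u2 = assays["u2"].to_numpy(float)
    bad = ~(np.isfinite(a1) & np.isfinite(u1) & np.isfinite(a2) & np.isfinite(u2))
    bad |= (a1 < 0) | (u1 < 0) | (a2 < 0) | (u2 < 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} assay rows have negative or non-finite areas/uncertainties"
        )
    x = np.maximum(a1 - u1, 0.0)
    y = np.maximum(a2 - u2, 0.0)
    intensity = x + y
    if inclusive_threshold:
        failed = intensity <= min_intensity
    else:
        failed = intensity < min_intensity
    failed |= (x == 0.0) & (y == 0.0)
    with np.errstate(invalid="ignore"):
        p = np.arctan2(y, x) / HALF_PI
    p[failed] = np.nan
    out = assays.copy()
    out["p"] = p
    out["intensity"] = intensity
    return out


def welch_statistic(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Unequal-variance t-statistic between two genotype clusters.

    |mean2 - mean1| / sqrt(sd1^2/n1 + sd2^2/n2); measures how cleanly the
    interval between two adjacent cluster means resolves genotypes.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("welch_statistic requires positive sample counts")
    se = math.sqrt(sd1 * sd1 / n1 + sd2 * sd2 / n2)
    if se == 0.0:
        raise ValueError("welch_statistic undefined for zero standard errors")
    return abs(mean2 - mean1) / se


@dataclass
class SnpParams:
    """Per-SNP calibration: cluster geometry, quality and error rates.

    ``tau_a`` / ``tau_b`` are Welch statistics for the (mu_aa, mu_ab) and
    (mu_ab, mu_bb) intervals.  ``f_b`` is the B-allele frequency in the
    reference parent set; ``eps_hat`` the estimated genotyping error rate
    and ``eps_tilde`` the assumed rate (floored).  A SNP is ``usable`` only
    when every class had enough calibration samples and the cluster means
    are strictly ordered.
    """

    snp_id: str
    mu_aa: float = float("nan")
    mu_ab: float = float("nan")
    mu_bb: float = float("nan")
    sigma_aa: float = float("nan")
    sigma_ab: float = float("nan")
    sigma_bb: float = float("nan")
    n_aa: int = 0
    n_ab: int = 0
    n_bb: int = 0
    tau_a: float = float("nan")
    tau_b: float = float("nan")
    f_b: float = float("nan")
    eps_hat: float = float("nan")
    eps_tilde: float = float("nan")
    usable: bool = False

    @property
    def mus(self) -> np.ndarray:
        return np.array([self.mu_aa, self.mu_ab, self.mu_bb])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_aa, self.sigma_ab, self.sigma_bb])

    @property
    def freq(self) -> np.ndarray:
        """Allele frequency vector (f_A, f_B); (0.5, 0.5) when unestimated."""
        if np.isfinite(self.f_b):
            return np.array([1.0 - self.f_b, self.f_b])
        return np.array([0.5, 0.5])


def calibrate_snp(
    p: Sequence[float] | np.ndarray,
    calls: Sequence[str | None],
    snp_id: str = "",
    min_class_n: int = DEFAULT_MIN_CLASS_N,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> SnpParams:
    """Estimate cluster means/SDs for one SNP from called calibration samples.

    Only samples with both a finite p and a platform call contribute.  A
    class with fewer than ``min_class_n`` samples, or cluster means that are
    not strictly increasing (AA < AB < BB), makes the SNP unusable.  Sample
    SDs use the n-1 denominator and are floored at ``sigma_floor``.
    """
    p = np.asarray(p, float)
    calls_arr = np.array([c if c in GENOTYPE_CLASSES else None for c in calls], object)
    params = SnpParams(snp_id=snp_id)
    stats: dict[str, tuple[float, float, int]] = {}
    for cls in GENOTYPE_CLASSES:
        sel = (calls_arr == cls) & np.isfinite(p)
        vals = p[sel]
        n = int(vals.size)
        if n >= 2:
            stats[cls] = (float(vals.mean()), max(float(vals.std(ddof=1)), sigma_floor), n)
        elif n == 1:
            stats[cls] = (float(vals[0]), sigma_floor, n)
        else:
            stats[cls] = (float("nan"), float("nan"), 0)
    (params.mu_aa, params.sigma_aa, params.n_aa) = stats["AA"]
    (params.mu_ab, params.sigma_ab, params.n_ab) = stats["AB"]
    (params.mu_bb, params.sigma_bb, params.n_bb) = stats["BB"]

    counts_ok = all(stats[c][2] >= min_class_n for c in GENOTYPE_CLASSES)
    ordered = counts_ok and (params.mu_aa < params.mu_ab < params.mu_bb)
    params.usable = bool(counts_ok and ordered)
    if params.usable:
        params.tau_a = welch_statistic(
            params.mu_aa, params.sigma_aa, params.n_aa,
            params.mu_ab, params.sigma_ab, params.n_ab,
        )
        params.tau_b = welch_statistic(
            params.mu_ab, params.sigma_ab, params.n_ab,
            params.mu_bb, params.sigma_bb, params.n_bb,
        )
    return params


def quantitative_genotype_matrix(p: float, params: SnpParams) -> np.ndarray | None:
    """2x2 ordered genotype probability matrix for one allelic proportion.

    Entries are proportional to the normal density heights of the three
    calibrated clusters at p, with the heterozygote height split equally
    between the (A,B) and (B,A) cells, then normalised to sum to one.
    Densities are combined in log space; if every log-density underflows the
    result is missing rather than artificially uniform.
    """
    if not params.usable or not np.isfinite(p):
        return None
    log_h = norm.logpdf(p, params.mus, params.sigmas)
    log_phi = np.array(
        [log_h[0], log_h[1] + math.log(0.5), log_h[1] + math.log(0.5), log_h[2]]
    )
    m = log_phi.max()
    if not np.isfinite(m):
        return None
    w = np.exp(log_phi - m)
    w /= w.sum()
    return np.array([[w[0], w[1]], [w[2], w[3]]])


def quantitative_matrices(p: np.ndarray, params: SnpParams) -> np.ndarray:
    """Vectorised quantitative matrices for one SNP; NaN blocks where missing."""
    p = np.asarray(p, float)
    out = np.full((p.size, 2, 2), np.nan)
    if not params.usable:
        return out
    ok = np.isfinite(p)
    if not ok.any():
        return out
    pv = p[ok]
    log_h = norm.logpdf(pv[:, None], params.mus[None, :], params.sigmas[None, :])
    log_phi = np.stack(
        [
            log_h[:, 0],
            log_h[:, 1] + math.log(0.5),
            log_h[:, 1] + math.log(0.5),
            log_h[:, 2],
        ],
        axis=1,
    )
    m = log_phi.max(axis=1, keepdims=True)
    finite = np.isfinite(m[:, 0])
    w = np.exp(log_phi - m)
    w /= w.sum(axis=1, keepdims=True)
    w[~finite] = np.nan
    out[ok] = w.reshape(-1, 2, 2)
    return out


def unordered_probabilities(g: np.ndarray) -> np.ndarray:
    """(P(AA), P(AB unordered), P(BB)) from a 2x2 ordered genotype matrix."""
    return np.array([g[0, 0], g[0, 1] + g[1, 0], g[1, 1]])


def discrete_genotype_matrix(
    g: np.ndarray | None, call_threshold: float = DEFAULT_CALL_THRESHOLD
) -> np.ndarray | None:
    """Discrete call matrix from a quantitative matrix, or missing.

    Unit mass goes to the most likely unordered genotype when its
    probability clears ``call_threshold``; a heterozygote is declared when
    either ordered heterozygote cell exceeds ``call_threshold / 2`` and its
    mass is stored split 0.5/0.5.  Below threshold the call is missing.
    """
    if g is None:
        return None
    het_threshold = call_threshold / 2.0
    if g[0, 0] > call_threshold:
        return np.array([[1.0, 0.0], [0.0, 0.0]])
    if g[1, 1] > call_threshold:
        return np.array([[0.0, 0.0], [0.0, 1.0]])
    if g[0, 1] > het_threshold or g[1, 0] > het_threshold:
        return np.array([[0.0, 0.5], [0.5, 0.0]])
    return None


def estimate_error_rates(
    g_matrices: np.ndarray | Iterable[np.ndarray | None],
    floor: float = DEFAULT_ERROR_FLOOR,
) -> tuple[float, float]:
    """(eps_hat, eps_tilde) for one SNP from its quantitative matrices.

    eps_hat is the mean, over samples with a genotype, of one minus the
    most likely unordered genotype probability; eps_tilde applies the floor.
    """
    if isinstance(g_matrices, np.ndarray) and g_matrices.ndim == 3:
        arr = g_matrices
    else:
        mats = [g for g in g_matrices if g is not None]
        if not mats:
            raise ValueError("estimate_error_rates needs at least one genotype matrix")
        arr = np.stack(mats)
    ok = np.isfinite(arr).all(axis=(1, 2))
    if not ok.any():
        raise ValueError("estimate_error_rates needs at least one non-missing matrix")
    arr = arr[ok]
    unordered = np.stack(
        [arr[:, 0, 0], arr[:, 0, 1] + arr[:, 1, 0], arr[:, 1, 1]], axis=1
    )
    eps_hat = float(np.mean(1.0 - unordered.max(axis=1)))
    eps_tilde = eps_hat if eps_hat > floor else floor
    return eps_hat, eps_tilde


def perturbed_genotype_matrix(
    d: np.ndarray | None, eps: float, freq: np.ndarray
) -> np.ndarray | None:
    """M = (1 - eps) D + eps F F': a discrete call blurred by error rate eps."""
    if d is None:
        return None
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"error rate {eps} outside [0, 1]")
    return (1.0 - eps) * d + eps * missing_parent_matrix(freq)


def missing_parent_matrix(freq: np.ndarray) -> np.ndarray:
    """Genotype matrix F F' for an ungenotyped parent (outer product of frequencies)."""
    f = np.asarray(freq, float)
    if f.shape != (2,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ValueError("allele frequency vector must be length 2, non-negative, sum 1")
    return np.outer(f, f)


def estimate_allele_frequencies(g_matrices: np.ndarray) -> float:
    """B-allele frequency from reference-sample genotype matrices.

    Each matrix contributes its expected B dosage / 2 — the mean of its
    B-row and B-column mass.  NaN when no sample has a genotype.
    """
    arr = np.asarray(g_matrices, float)
    ok = np.isfinite(arr).all(axis=(1, 2))
    if not ok.any():
        return float("nan")
    arr = arr[ok]
    b_mass = (arr[:, 1, :].sum(axis=1) + arr[:, :, 1].sum(axis=1)) / 2.0
    return float(b_mass.mean())


class GenotypeStore:
    """Dense container of genotype matrices: samples x SNPs x 2 x 2.

    Missing genotypes are NaN blocks.  ``kind`` records the matrix flavour
    (quantitative, discrete, perturbed_hat, perturbed_tilde).
    """

    def __init__(self, samples: Sequence[str], snps: Sequence[str],
                 G: np.ndarray, kind: str) -> None:
        self.samples = list(samples)
        self.snps = list(snps)
        if G.shape != (len(self.samples), len(self.snps), 2, 2):
            raise ValueError(f"G has shape {G.shape}, expected "
                             f"({len(self.samples)}, {len(self.snps)}, 2, 2)")
        self.G = G
        self.kind = kind
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._snp_index = {s: j for j, s in enumerate(self.snps)}

    def get(self, sample_id: str, snp_id: str) -> np.ndarray | None:
        g = self.G[self._sample_index[sample_id], self._snp_index[snp_id]]
        return None if np.isnan(g).any() else g

    def sample_rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self._sample_index[s] for s in sample_ids]
        return self.G[idx]

    def mask(self) -> np.ndarray:
        """Boolean (n_samples, n_snps): genotype present."""
        return np.isfinite(self.G).all(axis=(2, 3))


def build_genotype_store(
    proportions: pd.DataFrame,
    panel: Mapping[str, SnpParams],
    kind: str = "quantitative",
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
    samples: Sequence[str] | None = None,
) -> GenotypeStore:
    """Build a :class:`GenotypeStore` from an allelic-proportion table.

    ``proportions`` needs columns ``sample_id, snp_id, p``.  ``kind``
    selects the matrix flavour; perturbed flavours use the panel's per-SNP
    error rates (``perturbed_hat`` the estimated rate, ``perturbed_tilde``
    the floored assumed rate) and allele frequencies.
    """
    if kind not in ("quantitative", "discrete", "perturbed_hat", "perturbed_tilde"):
        raise ValueError(f"unknown genotype matrix kind {kind!r}")
    snps = [s for s in panel]
    if samples is None:
        samples = list(pd.unique(proportions["sample_id"]))
    n_samples, n_snps = len(samples), len(snps)
    sample_index = {s: i for i, s in enumerate(samples)}
    G = np.full((n_samples, n_snps, 2, 2), np.nan)
    by_snp = dict(tuple(proportions.groupby("snp_id", sort=False)))
    for j, snp in enumerate(snps):
        params = panel[snp]
        sub = by_snp.get(snp)
        if sub is None or not params.usable:
            continue
        rows = np.array([sample_index.get(s, -1) for s in sub["sample_id"]])
        keep = rows >= 0
        if not keep.any():
            continue
        gq = quantitative_matrices(sub["p"].to_numpy(float)[keep], params)
        if kind == "quantitative":
            G[rows[keep], j] = gq
        else:
            eps = params.eps_hat if kind == "perturbed_hat" else params.eps_tilde
            ff = missing_parent_matrix(params.freq)
            for r, g in zip(rows[keep], gq):
                if np.isnan(g).any():
                    continue
                d = discrete_genotype_matrix(g, call_threshold)
                if d is None:
                    continue
                if kind == "discrete":
                    G[r, j] = d
                else:
                    G[r, j] = (1.0 - eps) * d + eps * ff
    return GenotypeStore(samples, snps, G, kind)


def calibrate_panel(
    assays: pd.DataFrame,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
    min_class_n: int = DEFAULT_MIN_CLASS_N,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    error_floor: float = DEFAULT_ERROR_FLOOR,
    reference_samples: Sequence[str] | None = None,
) -> dict[str, SnpParams]:
    """Full per-SNP calibration from a raw assay table.

    Computes allelic proportions, per-SNP cluster parameters from the
    platform calls, then allele frequencies (from the quantitative matrices
    of ``reference_samples``; all samples when not given) and the two error
    rates.  Returns a dict snp_id -> :class:`SnpParams`.
    """
    props = allelic_proportions(assays, min_intensity=min_intensity)
    panel: dict[str, SnpParams] = {}
    for snp, sub in props.groupby("snp_id", sort=True):
        calls = sub["call"].tolist() if "call" in sub else [None] * len(sub)
        calls = [c if isinstance(c, str) and c in GENOTYPE_CLASSES else None for c in calls]
        params = calibrate_snp(
            sub["p"].to_numpy(float), calls, snp_id=str(snp),
            min_class_n=min_class_n, sigma_floor=sigma_floor,
        )
        if params.usable:
            ref = sub
            if reference_samples is not None:
                ref = sub[sub["sample_id"].isin(set(reference_samples))]
            gq_all = quantitative_matrices(sub["p"].to_numpy(float), params)
            gq_ref = quantitative_matrices(ref["p"].to_numpy(float), params)
            params.f_b = estimate_allele_frequencies(gq_ref)
            try:
                params.eps_hat, params.eps_tilde = estimate_error_rates(
                    gq_all, floor=error_floor
                )
            except ValueError:
                params.usable = False
        panel[str(snp)] = params
    return panel
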