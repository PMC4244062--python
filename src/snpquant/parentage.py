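"""Trio and pair likelihoods, LOD scores, exclusion counting, assignment.

Mendelian transmission is expressed in matrix form.  A parent's genotype
matrix G yields a transmission vector T = (G 1 + G' 1) / 2, the probability
of passing allele A or B.  For a candidate sire s and dam d, the outer
product T_s T_d' is the expected ordered-genotype distribution of their
offspring, and the trio likelihood at one marker is

    L = sum( (T_s T_d') o G_o )

with o the entrywise (Hadamard) product and G_o the offspring genotype
matrix.  The null likelihood replaces both parents with the
allele-frequency matrix F F'.  A trio's LOD is the sum over markers of
natural-log likelihood ratios, retained only when enough markers are
informative for every non-missing member.  Exclusion-based testing uses the
same algebra with discrete matrices: a mismatch is a marker where the trio
probability is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from snpquant.intensity import GenotypeStore, SnpParams, missing_parent_matrix

DEFAULT_MIN_SNPS = 10
DEFAULT_LOD_THRESHOLD = 3.0
DEFAULT_DELTA_THRESHOLD = 3.0

CATEGORIES = (
    "sire+dam",
    "sire+missing",
    "dam+missing",
    "either+missing",
    "both_missing",
)


def transmission_vector(g: np.ndarray) -> np.ndarray:
    """Allele transmission probabilities (A, B) from a genotype matrix.

    The mean of row and column sums; for the symmetric matrices produced
    here the two are equal, but the general form stays valid for asymmetric
    matrices (e.g. when parental origin of alleles is known).
    """
    return (g.sum(axis=1) + g.sum(axis=0)) / 2.0


def trio_marker_likelihood(
    t_sire: np.ndarray, t_dam: np.ndarray, g_off: np.ndarray
) -> float:
    """Single-marker trio likelihood sum((T_s T_d') o G_o) = T_s' G_o T_d."""
    return float(t_sire @ g_off @ t_dam)


def null_marker_likelihood(g_off: np.ndarray, freq: np.ndarray) -> float:
    """Marker likelihood with both parents unrelated (replaced by F F')."""
    f = np.asarray(freq, float)
    return float(f @ g_off @ f)


@dataclass
class TrioScore:
    """LOD score for one (offspring, sire?, dam?) combination."""

    offspring_id: str
    sire_id: str | None
    dam_id: str | None
    lod: float
    n_snps: int
    method: str = "quantitative"
    mismatches: int | None = None
    category: str | None = None


def trio_lod(
    offspring_id: str,
    sire_id: str | None,
    dam_id: str | None,
    store: GenotypeStore,
    freqs: Mapping[str, np.ndarray],
    min_snps: int = DEFAULT_MIN_SNPS,
) -> TrioScore | None:
    """LOD of one trio (or pair, with a missing parent) across the panel.

    Sums natural-log likelihood ratios over SNPs where every *named* member
    has a genotype; returns None when fewer than ``min_snps`` SNPs qualify.
    A missing parent is represented by the allele-frequency matrix, which
    contributes identically to numerator and null and so never biases the
    score; with both parents missing the LOD is exactly zero.
    """
    total = 0.0
    n = 0
    for snp in store.snps:
        g_off = store.get(offspring_id, snp)
        if g_off is None:
            continue
        f = freqs[snp]
        g_s = store.get(sire_id, snp) if sire_id is not None else None
        g_d = store.get(dam_id, snp) if dam_id is not None else None
        if sire_id is not None and g_s is None:
            continue
        if dam_id is not None and g_d is None:
            continue
        t_s = transmission_vector(g_s) if g_s is not None else np.asarray(f, float)
        t_d = transmission_vector(g_d) if g_d is not None else np.asarray(f, float)
        l1 = trio_marker_likelihood(t_s, t_d, g_off)
        l0 = null_marker_likelihood(g_off, f)
        if l0 <= 0.0:
            continue
        n += 1
        with np.errstate(divide="ignore"):
            total += np.log(l1) - np.log(l0)
    if n < min_snps:
        return None
    return TrioScore(offspring_id, sire_id, dam_id, float(total), n)


def resolve_trio(
    trio: TrioScore | None,
    sire_pair: TrioScore | None,
    dam_pair: TrioScore | None,
) -> TrioScore | None:
    """Trio-vs-pair fallback: keep the trio unless a pair score beats it.

    When the trio LOD is below the sire-offspring pair LOD the dam is
    assumed missing (and symmetrically for the dam).  Missing scores are
    treated as minus infinity; all missing gives None.
    """
    def lod(s: TrioScore | None) -> float:
        return s.lod if s is not None else -np.inf

    if trio is None and sire_pair is None and dam_pair is None:
        return None
    best_pair = sire_pair if lod(sire_pair) >= lod(dam_pair) else dam_pair
    if lod(trio) >= lod(best_pair):
        return trio
    return best_pair


def classify_assignment(
    trio_lod_value: float | None,
    sire_lod: float | None,
    dam_lod: float | None,
) -> str:
    """Assignment category from the trio, sire-pair and dam-pair LODs.

    sire+dam when the trio LOD is positive and exceeds both pair LODs;
    sire+missing when the sire-pair LOD is positive, exceeds the trio LOD,
    and the dam-pair LOD is below the trio LOD or negative (dam+missing
    symmetric); either+missing when both pair LODs are positive and both
    exceed the trio LOD; both_missing when every score is negative.
    """
    t = trio_lod_value if trio_lod_value is not None else -np.inf
    s = sire_lod if sire_lod is not None else -np.inf
    d = dam_lod if dam_lod is not None else -np.inf
    if t > 0 and t >= s and t >= d:
        return "sire+dam"
    if s > 0 and d > 0 and s > t and d > t:
        return "either+missing"
    if s > 0 and s > t and (d < t or d < 0):
        return "sire+missing"
    if d > 0 and d > t and (s < t or s < 0):
        return "dam+missing"
    return "both_missing"


def count_mismatches(
    d_sire: Sequence[np.ndarray | None],
    d_dam: Sequence[np.ndarray | None],
    d_off: Sequence[np.ndarray | None],
) -> int:
    """Exclusion mismatch count over SNPs from discrete genotype matrices.

    A mismatch is a SNP where the offspring genotype is Mendelian-impossible
    for the parent pair: sum((T_s T_d') o D_o) equals zero exactly.  SNPs
    with any missing member are skipped.
    """
    n = 0
    for ds, dd, do in zip(d_sire, d_dam, d_off):
        if ds is None or dd is None or do is None:
            continue
        if trio_marker_likelihood(transmission_vector(ds), transmission_vector(dd), do) == 0.0:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Vectorised scoring over all candidate sire x dam combinations
# ---------------------------------------------------------------------------


@dataclass
class TrioScoreSet:
    """All scores for one offspring against candidate sires and dams.

    ``trio_lod`` is (n_sires, n_dams), ``sire_lod``/``dam_lod`` the pair
    scores; NaN marks combinations failing the informative-SNP minimum.
    """

    offspring_id: str
    sires: list[str]
    dams: list[str]
    trio_lod: np.ndarray
    trio_n: np.ndarray
    sire_lod: np.ndarray
    sire_n: np.ndarray
    dam_lod: np.ndarray
    dam_n: np.ndarray
    mismatches: np.ndarray | None = None


def _transmission_stack(G: np.ndarray) -> np.ndarray:
    """Transmission vectors for a (n, n_snps, 2, 2) block -> (n, n_snps, 2)."""
    return (G.sum(axis=3) + G.sum(axis=2)) / 2.0


def score_trios(
    store: GenotypeStore,
    offspring_ids: Sequence[str],
    sire_ids: Sequence[str],
    dam_ids: Sequence[str],
    freqs: Mapping[str, np.ndarray],
    min_snps: int = DEFAULT_MIN_SNPS,
    count_exclusion_mismatches: bool = False,
) -> list[TrioScoreSet]:
    """Score every offspring against every candidate sire x dam pair.

    Equivalent to calling :func:`trio_lod` for every combination but
    evaluated with dense linear algebra: per SNP, trio likelihoods for all
    pairs are T_s' G_o T_d contracted over candidates at once.  Pair scores
    (one parent missing) are computed under the same informative-SNP rule,
    with the missing parent's transmission equal to the allele frequencies.
    With ``count_exclusion_mismatches`` (discrete store), per-pair mismatch
    counts are returned instead of meaningful likelihood magnitudes being
    the point — zero-likelihood SNPs are counted exactly.
    """
    F = np.stack([np.asarray(freqs[s], float) for s in store.snps])  # (J, 2)
    GS = store.sample_rows(sire_ids)  # (S, J, 2, 2)
    GD = store.sample_rows(dam_ids)
    ms = np.isfinite(GS).all(axis=(2, 3))  # (S, J)
    md = np.isfinite(GD).all(axis=(2, 3))
    TS = np.nan_to_num(_transmission_stack(GS))  # (S, J, 2)
    TD = np.nan_to_num(_transmission_stack(GD))

    results = []
    for off in offspring_ids:
        GO = store.sample_rows([off])[0]  # (J, 2, 2)
        mo = np.isfinite(GO).all(axis=(1, 2))
        GOc = np.nan_to_num(GO)
        l0 = np.einsum("ja,jab,jb->j", F, GOc, F)  # (J,)
        valid_snp = mo & (l0 > 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_l0 = np.log(l0)
            # trio: (S, D, J)
            half = np.einsum("sja,jab->sjb", TS, GOc)  # (S, J, 2)
            l1 = np.einsum("sjb,djb->sdj", half, TD)
            log_ratio = np.log(l1) - log_l0[None, None, :]
            # pairs
            l_sp = np.einsum("sjb,jb->sj", half, F)
            log_ratio_s = np.log(l_sp) - log_l0[None, :]
            l_dp = np.einsum("ja,jab,djb->dj", F, GOc, TD)
            log_ratio_d = np.log(l_dp) - log_l0[None, :]

        v_trio = valid_snp[None, None, :] & ms[:, None, :] & md[None, :, :]
        lod = np.where(v_trio, log_ratio, 0.0).sum(axis=2)
        n = v_trio.sum(axis=2)
        lod[n < min_snps] = np.nan

        v_s = valid_snp[None, :] & ms
        sire_lod = np.where(v_s, log_ratio_s, 0.0).sum(axis=1)
        sire_n = v_s.sum(axis=1)
        sire_lod[sire_n < min_snps] = np.nan

        v_d = valid_snp[None, :] & md
        dam_lod = np.where(v_d, log_ratio_d, 0.0).sum(axis=1)
        dam_n = v_d.sum(axis=1)
        dam_lod[dam_n < min_snps] = np.nan

        mism = None
        if count_exclusion_mismatches:
            mismatch_snp = (l1 == 0.0) & v_trio
            mism = mismatch_snp.sum(axis=2)

        results.append(
            TrioScoreSet(
                offspring_id=off,
                sires=list(sire_ids),
                dams=list(dam_ids),
                trio_lod=lod,
                trio_n=n,
                sire_lod=sire_lod,
                sire_n=sire_n,
                dam_lod=dam_lod,
                dam_n=dam_n,
                mismatches=mism,
            )
        )
    return results


def resolved_scores(scores: TrioScoreSet) -> tuple[np.ndarray, np.ndarray]:
    """Apply the trio-vs-pair fallback across a whole score set.

    Returns (resolved_lod, which) with ``which`` coded 0 = trio kept,
    1 = sire-pair fallback (dam missing), 2 = dam-pair fallback (sire
    missing); entries with no defined score are NaN / -1.
    """
    t = scores.trio_lod
    s = scores.sire_lod[:, None]
    d = scores.dam_lod[None, :]
    t_f = np.where(np.isnan(t), -np.inf, t)
    s_f = np.where(np.isnan(s), -np.inf, np.broadcast_to(s, t.shape))
    d_f = np.where(np.isnan(d), -np.inf, np.broadcast_to(d, t.shape))
    stacked = np.stack([t_f, s_f, d_f])
    # preference order on exact ties: trio, then sire-pair, then dam-pair
    which = stacked.argmax(axis=0)
    resolved = stacked.max(axis=0)
    none_defined = ~np.isfinite(resolved) & (resolved < 0)
    resolved[none_defined] = np.nan
    which = which.astype(int)
    which[none_defined] = -1
    return resolved, which


@dataclass
class RankedPairs:
    """Ranked candidate parent pairs for one offspring.

    ``pairs`` holds (sire_or_None, dam_or_None, score) sorted best-first
    (descending LOD, or ascending mismatches for exclusion); ``delta`` is
    the score gap between the best and the best *distinct* assignment.
    """

    offspring_id: str
    pairs: list[tuple[str | None, str | None, float]]
    delta: float
    assigned: bool
    method: str
    category: str | None = None

    @property
    def best(self) -> tuple[str | None, str | None, float] | None:
        return self.pairs[0] if self.pairs else None


def rank_parent_pairs(
    scores: TrioScoreSet,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    method: str = "quantitative",
    max_pairs: int | None = 10,
) -> RankedPairs:
    """Rank all candidate pairs for one offspring by resolved LOD.

    Pairs are resolved (trio-vs-pair fallback applied) then deduplicated to
    distinct assignments — many raw combinations can collapse onto the same
    sire+missing fallback.  Ties break lexicographically on (sire, dam) for
    determinism.  The offspring is flagged assigned when the best LOD
    exceeds ``lod_threshold`` and delta exceeds ``delta_threshold``.
    """
    resolved, which = resolved_scores(scores)
    entries: dict[tuple[str | None, str | None], float] = {}
    it = np.argwhere(~np.isnan(resolved))
    for i, j in it:
        w = which[i, j]
        if w == 0:
            key = (scores.sires[i], scores.dams[j])
        elif w == 1:
            key = (scores.sires[i], None)
        else:
            key = (None, scores.dams[j])
        val = resolved[i, j]
        if key not in entries or val > entries[key]:
            entries[key] = float(val)
    pairs = sorted(
        ((s, d, v) for (s, d), v in entries.items()),
        key=lambda x: (-x[2], x[0] or "", x[1] or ""),
    )
    if len(pairs) >= 2:
        delta = pairs[0][2] - pairs[1][2]
    elif len(pairs) == 1:
        delta = np.inf
    else:
        delta = 0.0
    assigned = bool(pairs) and pairs[0][2] > lod_threshold and delta > delta_threshold
    category = None
    if pairs:
        i_best = j_best = None
        s_best, d_best, _ = pairs[0]
        if s_best is not None:
            i_best = scores.sires.index(s_best)
        if d_best is not None:
            j_best = scores.dams.index(d_best)
        t = (
            scores.trio_lod[i_best, j_best]
            if i_best is not None and j_best is not None
            else np.nan
        )
        s_lod = scores.sire_lod[i_best] if i_best is not None else np.nan
        d_lod = scores.dam_lod[j_best] if j_best is not None else np.nan
        category = classify_assignment(
            None if np.isnan(t) else float(t),
            None if np.isnan(s_lod) else float(s_lod),
            None if np.isnan(d_lod) else float(d_lod),
        )
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    return RankedPairs(scores.offspring_id, pairs, float(delta), assigned, method, category)


def rank_parent_pairs_exclusion(
    scores: TrioScoreSet,
    max_mismatches: int = 0,
    max_pairs: int | None = 10,
) -> RankedPairs:
    """Rank candidate pairs by ascending exclusion mismatch count.

    Assigned when the minimum count is unique and within ``max_mismatches``.
    Requires a score set produced with ``count_exclusion_mismatches``.
    """
    if scores.mismatches is None:
        raise ValueError("score set has no mismatch counts; score with a discrete store")
    valid = ~np.isnan(scores.trio_lod)
    pairs = [
        (scores.sires[i], scores.dams[j], float(scores.mismatches[i, j]))
        for i, j in np.argwhere(valid)
    ]
    pairs.sort(key=lambda x: (x[2], x[0] or "", x[1] or ""))
    assigned = False
    delta = 0.0
    if pairs:
        best = pairs[0][2]
        n_at_best = sum(1 for p in pairs if p[2] == best)
        delta = (pairs[1][2] - best) if len(pairs) > 1 else np.inf
        assigned = best <= max_mismatches and n_at_best == 1
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    return RankedPairs(scores.offspring_id, pairs, float(delta), assigned, "exclusion")
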