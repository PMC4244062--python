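"""End-to-end pipeline: calibrate, assign, constrain, pool.

Stage order follows the method: per-SNP calibration from all individual
assays, genotype-matrix construction, trio/pair scoring and ranking for
each requested method, constrained pedigree search on the resolved scores,
then pooled-DNA allele frequencies and family-contribution estimation for
the pools.  Every stage logs its counts (usable SNPs, retained scores,
assignments, pools processed) and writes deterministic CSV/JSON artifacts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from snpquant import intensity, parentage, pedigree as pedsearch, pooling
from snpquant.intensity import GenotypeStore, SnpParams
from snpquant.io import RunConfig, write_json, write_panel, write_table

logger = logging.getLogger("snpquant")


def panel_freqs(panel: Mapping[str, SnpParams]) -> dict[str, np.ndarray]:
    return {snp: p.freq for snp, p in panel.items()}


def usable_panel(panel: Mapping[str, SnpParams]) -> dict[str, SnpParams]:
    return {s: p for s, p in panel.items() if p.usable}


def build_search_options(
    score_sets: Sequence[parentage.TrioScoreSet],
) -> dict[str, list[tuple[str | None, str | None, float]]]:
    """LOD option table for the pedigree search from raw score sets.

    Each offspring's options are all valid trios plus the sire-only and
    dam-only pair scores; the greedy search picking the best feasible
    option reproduces the trio-vs-pair fallback automatically.
    """
    options: dict[str, list[tuple[str | None, str | None, float]]] = {}
    for ss in score_sets:
        opts: list[tuple[str | None, str | None, float]] = []
        for i, j in np.argwhere(~np.isnan(ss.trio_lod)):
            opts.append((ss.sires[i], ss.dams[j], float(ss.trio_lod[i, j])))
        for i in np.flatnonzero(~np.isnan(ss.sire_lod)):
            opts.append((ss.sires[i], None, float(ss.sire_lod[i])))
        for j in np.flatnonzero(~np.isnan(ss.dam_lod)):
            opts.append((None, ss.dams[j], float(ss.dam_lod[j])))
        options[ss.offspring_id] = opts
    return options


def ranked_to_frame(ranked: Sequence[parentage.RankedPairs]) -> pd.DataFrame:
    rows = []
    for r in ranked:
        if r.best is None:
            rows.append(
                {
                    "offspring_id": r.offspring_id,
                    "sire_id": None,
                    "dam_id": None,
                    "method": r.method,
                    "lod": np.nan,
                    "delta": np.nan,
                    "assigned": False,
                    "category": None,
                }
            )
            continue
        s, d, v = r.best
        rows.append(
            {
                "offspring_id": r.offspring_id,
                "sire_id": s,
                "dam_id": d,
                "method": r.method,
                "lod": v,
                "delta": r.delta,
                "assigned": r.assigned,
                "category": r.category,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    assays: pd.DataFrame,
    offspring_ids: Sequence[str],
    sire_ids: Sequence[str],
    dam_ids: Sequence[str],
    config: RunConfig,
    outdir: str | Path | None = None,
    pool_members: pd.DataFrame | None = None,
    pool_assays: pd.DataFrame | None = None,
) -> dict:
    """Run every stage on an in-memory assay table; optionally write artifacts.

    ``assays`` must carry sample_id, snp_id, a1, u1, a2, u2, call.
    ``pool_members`` (pool_id, sample_id) and ``pool_assays`` (pool_id
    keyed, same area columns) switch on the pooled-DNA stages.
    Returns a dict of all intermediate and final results.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    config.log_settings()

    # -- calibration ------------------------------------------------------
    panel = intensity.calibrate_panel(
        assays,
        min_intensity=config.min_intensity,
        min_class_n=config.min_class_n,
        sigma_floor=config.sigma_floor,
        error_floor=config.error_floor,
        reference_samples=list(sire_ids) + list(dam_ids),
    )
    usable = usable_panel(panel)
    logger.info("calibrate: %d/%d SNPs usable", len(usable), len(panel))
    if out is not None:
        write_panel(panel, out / "panel.csv")

    props = intensity.allelic_proportions(assays, min_intensity=config.min_intensity)
    freqs = panel_freqs(usable)
    all_samples = list(offspring_ids) + list(sire_ids) + list(dam_ids)

    results: dict = {"panel": panel, "proportions": props}

    # -- scoring per method ----------------------------------------------
    method_rank: dict[str, list[parentage.RankedPairs]] = {}
    method_scores: dict[str, list[parentage.TrioScoreSet]] = {}
    for method in config.methods:
        kind = {"perturbed-hat": "perturbed_hat", "perturbed-tilde": "perturbed_tilde",
                "exclusion": "discrete"}.get(method, method)
        store = intensity.build_genotype_store(
            props, usable, kind=kind, call_threshold=config.call_threshold,
            samples=all_samples,
        )
        score_sets = parentage.score_trios(
            store, offspring_ids, sire_ids, dam_ids, freqs,
            min_snps=config.min_snps,
            count_exclusion_mismatches=(method == "exclusion"),
        )
        if method == "exclusion":
            ranked = [
                parentage.rank_parent_pairs_exclusion(
                    ss, max_mismatches=config.max_mismatches
                )
                for ss in score_sets
            ]
        else:
            ranked = [
                parentage.rank_parent_pairs(
                    ss,
                    lod_threshold=config.lod_threshold,
                    delta_threshold=config.delta_threshold,
                    method=method,
                )
                for ss in score_sets
            ]
        method_scores[method] = score_sets
        method_rank[method] = ranked
        n_assigned = sum(r.assigned for r in ranked)
        logger.info("assign[%s]: %d/%d offspring pass thresholds",
                    method, n_assigned, len(ranked))
    results["scores"] = method_scores
    results["ranked"] = method_rank
    if out is not None:
        frames = [ranked_to_frame(method_rank[m]) for m in config.methods]
        write_table(
            pd.concat(frames, ignore_index=True),
            out / "assignments.csv",
            sort_by=["method", "offspring_id"],
        )

    # -- constrained pedigree search --------------------------------------
    primary = config.methods[0]
    options = build_search_options(method_scores[primary])
    solution = pedsearch.stochastic_search(
        options, config.max_mates, n_restarts=config.restarts, seed=config.seed
    )
    summary = pedsearch.pedigree_summary(solution)
    logger.info("constrain: %d families, total LOD %.2f",
                summary["n_families"], summary["total_lod"])
    results["pedigree"] = solution
    results["pedigree_summary"] = summary
    if out is not None:
        ped_rows = [
            {"offspring_id": o, "sire_id": s, "dam_id": d}
            for o, (s, d) in solution.assignments.items()
        ]
        write_table(pd.DataFrame(ped_rows), out / "pedigree.csv",
                    sort_by=["offspring_id"])
        write_json(summary, out / "pedigree_summary.json")

    # -- pools -------------------------------------------------------------
    if pool_members is not None and pool_assays is not None:
        pool_freq, contrib = run_pool_stages(
            pool_assays, pool_members, props, usable, freqs, solution, config,
        )
        results["pool_frequencies"] = pool_freq
        results["contributions"] = contrib
        if out is not None:
            write_table(pool_freq, out / "pool_frequencies.csv",
                        sort_by=["pool_id", "snp_id"])
            write_table(contrib, out / "contributions.csv",
                        sort_by=["pool_id", "family_id"])
    return results


def run_pool_stages(
    pool_assays: pd.DataFrame,
    pool_members: pd.DataFrame,
    props: pd.DataFrame,
    panel: Mapping[str, SnpParams],
    freqs: Mapping[str, np.ndarray],
    solution: pedsearch.PedigreeSolution,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled allele frequencies and per-pool family contributions."""
    pa = pool_assays.rename(columns={"pool_id": "sample_id"})
    pool_props = intensity.allelic_proportions(
        pa, min_intensity=config.min_intensity, inclusive_threshold=True
    ).rename(columns={"sample_id": "pool_id"})
    snps = sorted(panel)

    member_p = props.set_index(["sample_id", "snp_id"])["p"]
    parent_ids = sorted(
        {p for s, d in solution.assignments.values() for p in (s, d) if p is not None}
    )
    parent_store = intensity.build_genotype_store(
        props, panel, kind="quantitative",
        call_threshold=config.call_threshold, samples=parent_ids,
    )

    freq_rows = []
    contrib_rows = []
    pool_props_idx = pool_props.set_index(["pool_id", "snp_id"])["p"]
    for pool_id, members in pool_members.groupby("pool_id"):
        member_ids = members["sample_id"].tolist()
        fams: dict[tuple[str | None, str | None], str] = {}
        for m in member_ids:
            pair = solution.assignments.get(m, (None, None))
            fams.setdefault(pair, f"{pair[0] or 'missing'}x{pair[1] or 'missing'}")
        family_pairs = sorted(fams, key=lambda t: (t[0] or "", t[1] or ""))
        X = pooling.family_frequency_matrix(family_pairs, parent_store, freqs)
        y = np.full(len(snps), np.nan)
        w = np.full(len(snps), np.nan)
        for j, snp in enumerate(snps):
            params = panel[snp]
            p_kj = pool_props_idx.get((pool_id, snp), np.nan)
            f_hat = pooling.pooled_allele_frequency(p_kj, params)
            tau = pooling.pool_weight(p_kj, params)
            mp = [member_p.get((m, snp), np.nan) for m in member_ids]
            f_star = pooling.individual_based_pool_frequency(mp, params)
            y[j] = f_hat
            w[j] = tau * tau if np.isfinite(f_hat) else np.nan
            freq_rows.append(
                {
                    "pool_id": pool_id,
                    "snp_id": snp,
                    "p_pool": p_kj,
                    "f_hat": f_hat,
                    "tau": tau,
                    "f_star": f_star,
                }
            )
        problem = pooling.build_contribution_problem(
            X, y, w, family_ids=[fams[t] for t in family_pairs]
        )
        est = pooling.estimate_contributions(problem)
        for (s, d), fid, b in zip(family_pairs, est.family_ids, est.beta):
            contrib_rows.append(
                {
                    "pool_id": pool_id,
                    "family_id": fid,
                    "sire_id": s,
                    "dam_id": d,
                    "beta": b,
                }
            )
    logger.info("pools: %d processed", pool_members["pool_id"].nunique())
    return pd.DataFrame(freq_rows), pd.DataFrame(contrib_rows)
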