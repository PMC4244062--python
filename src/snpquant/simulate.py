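"""Synthetic panels, pedigrees, raw assays and pools with known truth.

The generator emulates the geometry of a low-density multiplexed SNP panel:
per-SNP genotype clusters on the allelic-proportion axis with heterogeneous
means and spreads (heterozygote means allowed well off 0.5, homozygote
means off 0 and 1), platform call failures, per-assay missingness, and
pooled assays whose allelic proportion derives from the pool's true allele
frequency through the inverse of the piecewise calibration map.  Raw
channel areas are synthesized by inverting the polar transform, so that in
the noise-free limit the analysis pipeline recovers the simulated truth
exactly — a property the test-suite leans on.

Everything is driven by one seed; reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

GENO_CLASS = np.array(["AA", "AB", "BB"])


@dataclass
class SimulationConfig:
    """Study-scale defaults for a ~60-SNP biallelic aquaculture-style panel.

    Cluster mean ranges reproduce heterogeneous, off-centre clusters;
    intensity and uncertainty ranges are in platform area units, chosen so
    that a typical assay clears the minimum-intensity cutoff of 3 while a
    configurable fraction can be pushed below it.  Mating models:
    ``fullsib`` (disjoint parent pairs), ``halfsib2`` (each parent at most
    two mates) and ``random``.
    """

    n_snps: int = 58
    maf_range: tuple[float, float] = (0.1, 0.5)
    mu_aa_range: tuple[float, float] = (0.02, 0.15)
    mu_ab_range: tuple[float, float] = (0.35, 0.65)
    mu_bb_range: tuple[float, float] = (0.85, 0.98)
    cluster_sd_range: tuple[float, float] = (0.01, 0.03)
    intensity_range: tuple[float, float] = (5.0, 15.0)
    uncertainty_range: tuple[float, float] = (0.2, 1.0)
    missing_rate: float = 0.0
    call_failure_rate: float = 0.02
    n_sires: int = 60
    n_dams: int = 50
    n_families: int = 40
    offspring_per_family: int = 5
    mating_model: str = "fullsib"
    n_pools: int = 9
    pool_size_range: tuple[int, int] = (18, 26)
    families_per_pool: int | None = 12
    pool_family_concentration: float | None = None
    noise_sd_pool: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "call_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mating_model not in ("fullsib", "halfsib2", "random"):
            raise ValueError(f"unknown mating model {self.mating_model!r}")
        if not self.mu_aa_range[1] < self.mu_ab_range[0] < self.mu_ab_range[1] < self.mu_bb_range[0]:
            raise ValueError("cluster mean ranges must be ordered AA < AB < BB")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-SNP truth: B-allele frequency, cluster means and SDs."""
    rng = _rng(config, 0)
    n = config.n_snps
    snp_ids = [f"snp{j:03d}" for j in range(n)]
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "f_b": rng.uniform(*config.maf_range, n),
            "mu_aa": rng.uniform(*config.mu_aa_range, n),
            "mu_ab": rng.uniform(*config.mu_ab_range, n),
            "mu_bb": rng.uniform(*config.mu_bb_range, n),
            "sd_aa": rng.uniform(*config.cluster_sd_range, n),
            "sd_ab": rng.uniform(*config.cluster_sd_range, n),
            "sd_bb": rng.uniform(*config.cluster_sd_range, n),
        }
    )


def simulate_pedigree_and_genotypes(
    config: SimulationConfig, panel: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parents from Hardy-Weinberg, matings per model, Mendelian offspring.

    Returns (pedigree, genotypes): pedigree has one row per offspring with
    its true sire, dam and family id; genotypes holds B-allele dosages
    (0/1/2) for every sample (parents and offspring) by SNP, samples in
    rows, SNPs in columns.
    """
    rng = _rng(config, 1)
    f_b = panel["f_b"].to_numpy()
    n_snps = len(f_b)
    sires = [f"S{i:03d}" for i in range(config.n_sires)]
    dams = [f"D{i:03d}" for i in range(config.n_dams)]
    sire_geno = rng.binomial(2, f_b, size=(config.n_sires, n_snps))
    dam_geno = rng.binomial(2, f_b, size=(config.n_dams, n_snps))

    matings = _draw_matings(config, rng)
    rows = []
    off_geno = []
    off_ids = []
    k = 0
    for fam, (si, di) in enumerate(matings):
        for _ in range(config.offspring_per_family):
            oid = f"O{k:04d}"
            k += 1
            # one allele from each parent: Bernoulli(dosage / 2)
            from_sire = rng.random(n_snps) < sire_geno[si] / 2.0
            from_dam = rng.random(n_snps) < dam_geno[di] / 2.0
            off_geno.append(from_sire.astype(int) + from_dam.astype(int))
            off_ids.append(oid)
            rows.append(
                {
                    "offspring_id": oid,
                    "sire_id": sires[si],
                    "dam_id": dams[di],
                    "family_id": f"F{fam:03d}",
                }
            )
    pedigree = pd.DataFrame(rows)
    genotypes = pd.DataFrame(
        np.vstack([sire_geno, dam_geno, np.vstack(off_geno)]),
        index=sires + dams + off_ids,
        columns=panel["snp_id"].tolist(),
    )
    genotypes.index.name = "sample_id"
    return pedigree, genotypes


def _draw_matings(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n_fam = config.n_families
    if config.mating_model == "fullsib":
        if n_fam > config.n_sires or n_fam > config.n_dams:
            raise ValueError("not enough parents for disjoint full-sib families")
        si = rng.permutation(config.n_sires)[:n_fam]
        di = rng.permutation(config.n_dams)[:n_fam]
        return list(zip(si.tolist(), di.tolist()))
    max_mates = 2 if config.mating_model == "halfsib2" else None
    if max_mates is not None and (
        n_fam > max_mates * config.n_sires or n_fam > max_mates * config.n_dams
    ):
        raise ValueError("not enough parents for the requested half-sib families")
    matings: list[tuple[int, int]] = []
    used: set[tuple[int, int]] = set()
    sire_ct = np.zeros(config.n_sires, int)
    dam_ct = np.zeros(config.n_dams, int)
    while len(matings) < n_fam:
        si = int(rng.integers(config.n_sires))
        di = int(rng.integers(config.n_dams))
        if (si, di) in used:
            continue
        if max_mates is not None and (sire_ct[si] >= max_mates or dam_ct[di] >= max_mates):
            continue
        used.add((si, di))
        sire_ct[si] += 1
        dam_ct[di] += 1
        matings.append((si, di))
    return matings


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """N(mean, sd) truncated to [0, 1], elementwise; sd = 0 returns the mean."""
    sd = np.asarray(sd, float)
    mean = np.asarray(mean, float)
    out = mean.copy()
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        b = (1.0 - mean[pos]) / sd[pos]
        out[pos] = truncnorm.rvs(a, b, loc=mean[pos], scale=sd[pos], random_state=rng)
    return out


def _areas_from_p(
    rng: np.random.Generator, p: np.ndarray, config: SimulationConfig
) -> pd.DataFrame:
    """Invert the polar transform: p and a drawn intensity to channel areas.

    Adjusted areas are (r cos(p pi/2), r sin(p pi/2)); drawn uncertainties
    are added back so that subtracting them recovers the adjusted areas —
    and hence p — exactly.
    """
    r = rng.uniform(*config.intensity_range, p.size)
    theta = p * np.pi / 2.0
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    u1 = rng.uniform(*config.uncertainty_range, p.size)
    u2 = rng.uniform(*config.uncertainty_range, p.size)
    return pd.DataFrame(
        {"a1": x + u1, "u1": u1, "a2": y + u2, "u2": u2, "true_intensity": r}
    )


def simulate_assays(
    genotypes: pd.DataFrame, panel: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Raw individual assay table for every (sample, SNP).

    Per assay the allelic proportion is drawn from the truncated normal of
    the sample's true genotype cluster, then converted to channel areas.
    The platform call is the true class except at ``call_failure_rate``
    (call set missing); whole assays are dropped at ``missing_rate``.
    Truth columns (``true_p``, ``true_geno``) ride along for testing and
    are not part of the assay file contract.
    """
    rng = _rng(config, 2)
    samples = genotypes.index.to_numpy()
    snps = panel["snp_id"].to_numpy()
    n_s, n_j = len(samples), len(snps)
    dosage = genotypes.to_numpy()  # (n_s, n_j)
    mus = panel[["mu_aa", "mu_ab", "mu_bb"]].to_numpy()  # (n_j, 3)
    sds = panel[["sd_aa", "sd_ab", "sd_bb"]].to_numpy()
    mean = np.take_along_axis(mus.T[None, :, :], dosage[:, None, :], axis=1)[:, 0, :]
    sd = np.take_along_axis(sds.T[None, :, :], dosage[:, None, :], axis=1)[:, 0, :]
    p = _truncated_normal(rng, mean.ravel(), sd.ravel())
    areas = _areas_from_p(rng, p, config)
    calls = GENO_CLASS[dosage.ravel()].astype(object)
    failed = rng.random(p.size) < config.call_failure_rate
    calls[failed] = None
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, n_j),
            "snp_id": np.tile(snps, n_s),
            "call": calls,
            "true_p": p,
            "true_geno": GENO_CLASS[dosage.ravel()],
        }
    )
    df = pd.concat([df, areas], axis=1)
    if config.missing_rate > 0:
        keep = rng.random(len(df)) >= config.missing_rate
        df = df[keep].reset_index(drop=True)
    cols = ["sample_id", "snp_id", "a1", "u1", "a2", "u2", "call",
            "true_p", "true_geno", "true_intensity"]
    return df[cols]


def assign_pools(
    pedigree: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Pool membership table: offspring drawn into pools of study-like size.

    When ``pool_family_concentration`` is set, per-pool family weights are
    drawn from a symmetric Dirichlet with that concentration and member
    counts from the corresponding multinomial, giving deliberately uneven
    family contributions (small concentrations make a few families
    dominate each pool, as in commercial tanks).  Otherwise, when
    ``families_per_pool`` is set, each pool samples its members from that
    many randomly chosen families (as evenly as the draw allows); with
    neither, members are drawn at random across all offspring.  Sampling
    is without replacement within a pool.
    """
    rng = _rng(config, 3)
    rows = []
    fam_groups = {f: g["offspring_id"].tolist() for f, g in pedigree.groupby("family_id")}
    all_off = pedigree["offspring_id"].tolist()
    for k in range(config.n_pools):
        size = int(rng.integers(config.pool_size_range[0], config.pool_size_range[1] + 1))
        if config.pool_family_concentration is not None:
            fams = sorted(fam_groups)
            weights = rng.dirichlet(
                np.full(len(fams), config.pool_family_concentration)
            )
            counts = rng.multinomial(size, weights)
            members = []
            for fam, count in zip(fams, counts):
                take = min(count, len(fam_groups[fam]))
                if take:
                    members.extend(
                        str(m)
                        for m in rng.choice(fam_groups[fam], size=take, replace=False)
                    )
        elif config.families_per_pool:
            fams = list(fam_groups)
            n_fam = min(config.families_per_pool, len(fams))
            chosen = rng.choice(len(fams), size=n_fam, replace=False)
            members: list[str] = []
            candidates = [list(fam_groups[fams[i]]) for i in chosen]
            fi = 0
            while len(members) < size and any(candidates):
                group = candidates[fi % n_fam]
                if group:
                    pick = int(rng.integers(len(group)))
                    members.append(group.pop(pick))
                fi += 1
        else:
            members = list(
                rng.choice(all_off, size=min(size, len(all_off)), replace=False)
            )
        rows.extend({"pool_id": f"P{k:02d}", "sample_id": m} for m in members)
    return pd.DataFrame(rows)


def true_pool_frequencies(
    pools: pd.DataFrame, genotypes: pd.DataFrame, snps: Sequence[str]
) -> pd.DataFrame:
    """True per-pool B-allele frequency: mean member dosage / 2."""
    rows = []
    for pool_id, g in pools.groupby("pool_id"):
        dos = genotypes.loc[g["sample_id"], list(snps)].to_numpy()
        freq = dos.mean(axis=0) / 2.0
        rows.append(pd.Series(freq, index=list(snps), name=pool_id))
    out = pd.DataFrame(rows)
    out.index.name = "pool_id"
    return out


def simulate_pool_assays(
    pools: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled assay table plus the true per-pool family contributions.

    The true pool B frequency maps to an allelic proportion through the
    inverse piecewise calibration map anchored at the panel-truth cluster
    means, perturbed by N(0, noise_sd_pool) truncated to [0, 1], then
    synthesized into channel areas exactly as for individuals.
    """
    rng = _rng(config, 4)
    snps = panel["snp_id"].tolist()
    truth_f = true_pool_frequencies(pools, genotypes, snps)
    mus = panel[["mu_aa", "mu_ab", "mu_bb"]].to_numpy()
    records = []
    for pool_id, frow in truth_f.iterrows():
        f = frow.to_numpy()
        p = np.array(
            [
                np.interp(fj, [0.0, 0.5, 1.0], [mus[j, 0], mus[j, 1], mus[j, 2]])
                for j, fj in enumerate(f)
            ]
        )
        if config.noise_sd_pool > 0:
            p = _truncated_normal(
                rng, p, np.full_like(p, config.noise_sd_pool)
            )
        areas = _areas_from_p(rng, p, config)
        sub = pd.DataFrame(
            {
                "sample_id": pool_id,
                "snp_id": snps,
                "call": None,
                "true_p": p,
                "true_f": f,
            }
        )
        records.append(pd.concat([sub, areas], axis=1))
    assays = pd.concat(records, ignore_index=True)
    assays = assays[
        ["sample_id", "snp_id", "a1", "u1", "a2", "u2", "call", "true_p", "true_f"]
    ].rename(columns={"sample_id": "pool_id"})
    return assays, _true_contributions(pools)


def _true_contributions(pools: pd.DataFrame) -> pd.DataFrame:
    counts = (
        pools.groupby(["pool_id", "family_id"]).size().rename("n_members").reset_index()
        if "family_id" in pools
        else None
    )
    if counts is None:
        raise ValueError(
            "pool membership table needs a family_id column to compute "
            "true contributions; merge with the pedigree first"
        )
    totals = counts.groupby("pool_id")["n_members"].transform("sum")
    counts["contribution"] = counts["n_members"] / totals
    return counts


def simulate_dataset(config: SimulationConfig) -> dict:
    """End-to-end simulation: panel, pedigree, assays, pools, all truth.

    Returns a dict with keys ``panel, pedigree, genotypes, assays, pools,
    pool_assays, contributions`` — everything the pipeline needs plus the
    truth to validate against.
    """
    panel = simulate_panel(config)
    pedigree, genotypes = simulate_pedigree_and_genotypes(config, panel)
    assays = simulate_assays(genotypes, panel, config)
    pools = assign_pools(pedigree, config)
    pools = pools.merge(
        pedigree[["offspring_id", "family_id"]],
        left_on="sample_id",
        right_on="offspring_id",
    ).drop(columns="offspring_id")
    pool_assays, contributions = simulate_pool_assays(pools, genotypes, panel, config)
    return {
        "panel": panel,
        "pedigree": pedigree,
        "genotypes": genotypes,
        "assays": assays,
        "pools": pools,
        "pool_assays": pool_assays,
        "contributions": contributions,
    }
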