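"""Synthetic pedigree, genotype, and litter-trait generator.

The simulator emulates the structure of a closed pig nucleus herd with
repeated litter records: a multi-generation pedigree under hierarchical
random mating, biallelic autosomal SNPs dropped through the pedigree with
Haldane recombination (1 cM/Mb) so LD decays with distance, and phenotypes
following the repeatability animal model y = Xb + Za + Wpe + e.  Additive
values combine marker-QTL effects (scaled to requested variance fractions)
with a pedigree polygenic remainder; defaults target the variance components
of a lowly heritable litter trait (0.9 / 0.68 / 5.49, h² ≈ 0.13).

All randomness flows through one seed; identical configs and seeds give
identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from singlestep.genotypes import MarkerData
from singlestep.pedigree import Pedigree, inbreeding
from singlestep.reml import TraitDataset

#: Haldane map expansion, Morgans per bp (1 cM / Mb)
MORGAN_PER_BP = 1e-8


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Variance targets default to the components of a total-born-type litter
    trait (h² ≈ 0.13) with a permanent-environment effect per sow and a
    large residual; the genome is 18 autosomes.
    """

    n_founders: int = 80
    n_generations: int = 3
    dams_per_sire: int = 4
    offspring_per_dam: int = 4
    n_chromosomes: int = 18
    chrom_length_bp: int = 100_000_000
    n_markers: int = 1_800
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 0
    qtl_variance_fractions: tuple[float, ...] = ()
    sigma_a2: float = 0.9
    sigma_pe2: float = 0.68
    sigma_e2: float = 5.49
    n_parities: int = 3
    n_year_seasons: int = 8
    parity_effect_sd: float = 0.3
    year_season_effect_sd: float = 0.3
    mean_value: float = 10.5
    genotyping_fraction: float = 0.6
    integerize_phenotypes: bool = False
    polygenic_background: str = "markers"  # or "pedigree"
    morgans_per_bp: float = MORGAN_PER_BP
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.genotyping_fraction <= 1.0:
            raise ValueError("genotyping_fraction must be in [0, 1]")
        if sum(self.qtl_variance_fractions) > 1.0 + 1e-12:
            raise ValueError("QTL variance fractions must sum to <= 1")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if len(self.qtl_variance_fractions) not in (0, self.n_qtl):
            raise ValueError("qtl_variance_fractions must have n_qtl entries (or none)")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for recovery tests: true breeding values, QTL placement,
    permanent-environment effects, and the realized heritability."""

    true_bv: pd.Series
    qtl: pd.DataFrame
    true_pe: pd.Series
    realized_h2: float
    fixed_effects: dict = field(default_factory=dict)


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Discrete-generation pedigree under hierarchical mating.

    Each generation samples sires from the previous generation's males, each
    mated to ``dams_per_sire`` dams with ``offspring_per_dam`` offspring of
    alternating sex.  Returns ``(Pedigree, meta)`` with per-animal
    generation and sex in ``meta``.
    """
    rng = rng or _rng(cfg)
    records: list[tuple[str, str, str]] = []
    meta_rows = []
    males: list[str] = []
    females: list[str] = []
    for i in range(cfg.n_founders):
        aid = f"G0_{i:05d}"
        sex = "M" if i % 2 == 0 else "F"
        (males if sex == "M" else females).append(aid)
        records.append((aid, "0", "0"))
        meta_rows.append((aid, 0, sex))
    for g in range(1, cfg.n_generations + 1):
        n_dams = len(females)
        n_sires = max(1, int(np.ceil(n_dams / cfg.dams_per_sire)))
        sires = list(rng.choice(males, size=min(n_sires, len(males)), replace=False))
        dam_order = list(rng.permutation(females))
        next_m: list[str] = []
        next_f: list[str] = []
        k = 0
        for di, dam in enumerate(dam_order):
            sire = sires[di % len(sires)]
            for _ in range(cfg.offspring_per_dam):
                aid = f"G{g}_{k:05d}"
                sex = "M" if k % 2 == 0 else "F"  # balanced across the cohort
                k += 1
                (next_m if sex == "M" else next_f).append(aid)
                records.append((aid, sire, dam))
                meta_rows.append((aid, g, sex))
        males, females = next_m, next_f
    ped = Pedigree.from_records(records)
    meta = pd.DataFrame(meta_rows, columns=["animal_id", "generation", "sex"])
    return ped, meta


def _marker_map(cfg: SimConfig, rng: np.random.Generator):
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    chrom, pos = [], []
    for c in range(cfg.n_chromosomes):
        p = np.sort(rng.choice(cfg.chrom_length_bp - 1, size=per[c], replace=False)) + 1
        chrom.extend([str(c + 1)] * per[c])
        pos.extend(p.tolist())
    return np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> MarkerData:
    """Gene-drop genotypes for every pedigree animal.

    Founder haplotype alleles are independent Bernoulli draws at per-marker
    frequencies from ``maf_range``; gametes recombine between adjacent
    markers with Haldane probability r = (1 − exp(−2d))/2 at 1 cM/Mb, so LD
    builds up through transmission and decays with distance.
    """
    rng = rng or _rng(cfg)
    chrom, pos = _marker_map(cfg, rng)
    m = len(pos)
    p0 = rng.uniform(*cfg.maf_range, size=m)
    n = ped.n
    hap = np.zeros((n, 2, m), dtype=np.int8)

    # switch probability between adjacent markers (1 across chromosome breaks)
    dist = np.diff(pos).astype(float) * cfg.morgans_per_bp
    switch = 0.5 * (1.0 - np.exp(-2.0 * dist))
    new_chrom = np.array([chrom[i + 1] != chrom[i] for i in range(m - 1)])
    switch[new_chrom] = 0.5

    def gamete(parent: int) -> np.ndarray:
        flips = rng.random(m - 1) < switch
        src = np.empty(m, dtype=np.int64)
        src[0] = rng.integers(2)
        src[1:] = np.where(flips, 1, 0)
        np.cumsum(src, out=src)
        src &= 1
        return hap[parent, src, np.arange(m)]

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for hx, par in enumerate((s, d)):
            if par < 0:
                hap[i, hx] = rng.random(m) < p0
            else:
                hap[i, hx] = gamete(int(par))
    calls = hap.sum(axis=1).astype(float)
    ids = tuple(f"M{c}_{j:05d}" for j, c in enumerate(chrom))
    return MarkerData(sample_ids=tuple(ped.ids), marker_ids=ids,
                      chrom=chrom, pos=pos, calls=calls)


def _polygenic(ped: Pedigree, var: float, rng: np.random.Generator) -> np.ndarray:
    """Breeding values by pedigree recursion with Mendelian sampling."""
    F = inbreeding(ped)
    u = np.zeros(ped.n)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            mid = 0.5 * (u[s] + u[d])
            mvar = (0.5 - 0.25 * (F[s] + F[d])) * var
        elif s >= 0 or d >= 0:
            par = s if s >= 0 else d
            mid = 0.5 * u[par]
            mvar = (0.75 - 0.25 * F[par]) * var
        else:
            mid, mvar = 0.0, var
        u[i] = mid + rng.normal(0.0, np.sqrt(mvar))
    return u


def simulate_phenotypes(
    ped: Pedigree,
    md: MarkerData,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    meta: pd.DataFrame | None = None,
):
    """Litter-trait records under the repeatability animal model.

    True breeding values are QTL effects at randomly chosen markers (each
    scaled to its requested share of ``sigma_a2``) plus a polygenic
    remainder; every non-founder female gets ``n_parities`` records with a
    shared permanent-environment effect, random year-season levels, parity
    and year-season fixed effects, and iid residuals.  Returns
    ``(TraitDataset, SimTruth)``.
    """
    rng = rng or _rng(cfg)
    n = ped.n
    a = np.zeros(n)
    qtl_rows = []
    frac_qtl = 0.0
    if cfg.n_qtl:
        fracs = (cfg.qtl_variance_fractions
                 or tuple([1.0 / cfg.n_qtl] * cfg.n_qtl))
        qtl_idx = rng.choice(md.n_markers, size=cfg.n_qtl, replace=False)
        sample_pos = {s: i for i, s in enumerate(md.sample_ids)}
        rows = np.array([sample_pos[aid] for aid in ped.ids])
        for j, frac in zip(qtl_idx, fracs):
            w = md.calls[rows, j]
            vw = np.var(w)
            if vw <= 0:
                continue
            eff = np.sqrt(frac * cfg.sigma_a2 / vw) * rng.choice([-1.0, 1.0])
            a += (w - w.mean()) * eff
            frac_qtl += frac
            qtl_rows.append((md.marker_ids[j], int(j), str(md.chrom[j]),
                             int(md.pos[j]), float(eff), float(frac)))
    var_poly = max(0.0, (1.0 - frac_qtl)) * cfg.sigma_a2
    if var_poly > 0:
        if cfg.polygenic_background == "markers":
            # genome-wide background: small effects at every non-QTL marker,
            # so the polygenic term lives on the same genome the panel tags
            sample_pos = {s: i for i, s in enumerate(md.sample_ids)}
            rows = np.array([sample_pos[aid] for aid in ped.ids])
            bg = np.setdiff1d(np.arange(md.n_markers),
                              np.array([r[1] for r in qtl_rows], dtype=int))
            alpha = rng.normal(0.0, 1.0, size=bg.size)
            g = md.calls[np.ix_(rows, bg)] @ alpha
            g -= g.mean()
            vg = np.var(g)
            if vg > 0:
                a += g * np.sqrt(var_poly / vg)
        else:
            a += _polygenic(ped, var_poly, rng)

    if meta is None:
        gen = np.array([0 if s < 0 and d < 0 else 1
                        for s, d in zip(ped.sire, ped.dam)])
        sex = np.array(["F" if i % 2 else "M" for i in range(n)])
        meta = pd.DataFrame({"animal_id": ped.ids, "generation": gen, "sex": sex})
    meta = meta.set_index("animal_id").loc[list(ped.ids)].reset_index()
    sows = meta[(meta["generation"] >= 1) & (meta["sex"] == "F")]["animal_id"]
    sows = [str(s) for s in sows]

    parity_eff = rng.normal(0.0, cfg.parity_effect_sd, size=cfg.n_parities)
    ys_eff = rng.normal(0.0, cfg.year_season_effect_sd, size=cfg.n_year_seasons)
    pe = rng.normal(0.0, np.sqrt(cfg.sigma_pe2), size=len(sows))

    recs = []
    for si, sow in enumerate(sows):
        ai = ped.index[sow]
        for par in range(cfg.n_parities):
            ys = int(rng.integers(cfg.n_year_seasons))
            e = rng.normal(0.0, np.sqrt(cfg.sigma_e2))
            y = cfg.mean_value + parity_eff[par] + ys_eff[ys] + a[ai] + pe[si] + e
            if cfg.integerize_phenotypes:
                y = max(0.0, round(y))
            recs.append((sow, par + 1, f"YS{ys}", y))
    records = pd.DataFrame(recs, columns=["animal_id", "parity", "year_season", "value"])
    data = TraitDataset(records=records)

    sow_a = np.array([a[ped.index[s]] for s in sows])
    var_y = float(np.var(records["value"]))
    realized_h2 = float(np.var(sow_a) / var_y) if var_y > 0 else float("nan")
    truth = SimTruth(
        true_bv=pd.Series(a, index=list(ped.ids), name="true_bv"),
        qtl=pd.DataFrame(qtl_rows, columns=["marker", "index", "chrom", "pos",
                                            "effect", "variance_fraction"]),
        true_pe=pd.Series(pe, index=sows, name="true_pe"),
        realized_h2=realized_h2,
        fixed_effects={"parity": parity_eff.tolist(),
                       "year_season": ys_eff.tolist()},
    )
    return data, truth


@dataclass(frozen=True)
class SimBundle:
    """One complete simulated study: pedigree, genotypes, records, truth."""

    ped: Pedigree
    meta: pd.DataFrame
    markers_all: MarkerData
    markers_genotyped: MarkerData
    data: TraitDataset
    truth: SimTruth
    cfg: SimConfig


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """Run the full generator with one seeded stream.

    The genotyped subset is a random draw of ``genotyping_fraction`` of the
    recorded sows (the analysis-facing marker set); ``markers_all`` keeps
    every pedigree animal for truth-based checks.
    """
    rng = _rng(cfg)
    ped, meta = simulate_pedigree(cfg, rng)
    md_all = simulate_genotypes(ped, cfg, rng)
    data, truth = simulate_phenotypes(ped, md_all, cfg, rng, meta=meta)
    sows = data.animals
    n_g = int(round(cfg.genotyping_fraction * len(sows)))
    genotyped = sorted(rng.choice(sows, size=n_g, replace=False).tolist())
    md_g = md_all.take_samples(genotyped)
    return SimBundle(ped=ped, meta=meta, markers_all=md_all,
                     markers_genotyped=md_g, data=data, truth=truth, cfg=cfg)
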