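"""Weighted single-step GWAS: SNP effects from GEBVs, iterative
re-weighting, and window variance scans.

The loop follows the classic iterative scheme: start with equal SNP
weights (D = I), build G = Z D Z' lam, solve the single-step MME for GEBVs,
back-solve SNP effects u = lam D Z' G⁻¹ a_g for the genotyped animals,
re-weight each SNP by d_i = u_i^2 2 p_i (1 - p_i), rescale D to constant
trace, and repeat.  The scan statistic is the percentage of additive genetic
variance explained by sliding windows of consecutive SNPs within a fixed
span (default 0.52 Mb, an LD-decay-derived choice), and windows at or above
1.56% (a 50-fold enrichment over the expected per-window share) are called
significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from singlestep.genotypes import MarkerData, gene_content_centered
from singlestep.kinship import SnpWeights, blend, genomic_matrix, h_inverse
from singlestep.pedigree import Pedigree, a_inverse, numerator_matrix
from singlestep.reml import TraitDataset, VarianceComponents
from singlestep.ssgblup import MmeSolution, solve_mme


@dataclass(frozen=True)
class WssgwasConfig:
    window_bp: int = 520_000
    n_iterations: int = 3
    sig_threshold_pct: float = 1.56
    threshold_fold: float = 50.0
    blend_tau: float = 0.95
    weight_floor: float = 1e-8
    scan_ddof: int = 0  # population variance across individuals

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class SnpEffectSet:
    """Back-solved SNP effects u at one re-weighting iteration."""

    u_hat: np.ndarray
    iteration: int
    trait: str = ""
    gebv_g: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)

    @property
    def n_markers(self) -> int:
        return len(self.u_hat)


@dataclass(frozen=True)
class WindowVariance:
    """Per-anchor sliding-window share of additive genetic variance (%).

    ``windows`` columns: chrom, start_bp, end_bp, anchor, n_snp, pct_var,
    first_idx, last_idx (marker index range of the window).
    """

    windows: pd.DataFrame
    sigma_a2: float
    window_bp: int


def _backsolve_minnorm(a_hat_g: np.ndarray, Z: np.ndarray, d: np.ndarray, lam: float):
    """u = lam D Z' G⁺ a_g via the SVD of B = Z (lam D)^(1/2).

    Because Z is column-centered, G = B B' always has the all-ones vector in
    its null space; the pseudo-inverse route reproduces the *centered* GEBVs
    exactly (Z u equals a_g projected onto range(G), i.e. a_g minus its
    base constant) without squaring the condition number.  Returns
    ``(u, rank)``.
    """
    s = np.sqrt(lam * d)
    B = Z * s
    U, sig, Vt = la.svd(B, full_matrices=False)
    keep = sig > (sig.max() * 1e-12 if sig.size else 0.0)
    v = Vt[keep].T @ ((U[:, keep].T @ a_hat_g) / sig[keep])
    return s * v, int(keep.sum())


def backsolve_snp_effects(
    a_hat_g: np.ndarray,
    Z: np.ndarray,
    weights: SnpWeights | np.ndarray,
    Ginv: np.ndarray,
    lam: float,
    iteration: int = 1,
) -> SnpEffectSet:
    """u = lam D Z' G⁻¹ a_g.

    With ``Ginv`` the exact inverse of the *unblended* G = Z D Z' lam, the
    reconstruction Z u = a_g is an algebraic identity.
    """
    d = weights.d if isinstance(weights, SnpWeights) else np.asarray(weights, dtype=float)
    a_hat_g = np.asarray(a_hat_g, dtype=float)
    if Z.shape[0] != a_hat_g.shape[0] or Z.shape[1] != d.shape[0]:
        raise ValueError("dimension mismatch between Z, weights, and GEBVs")
    u = lam * d * (Z.T @ (Ginv @ a_hat_g))
    return SnpEffectSet(u_hat=u, iteration=iteration, gebv_g=a_hat_g.copy())


def update_weights(u: SnpEffectSet | np.ndarray, p: np.ndarray) -> np.ndarray:
    """Raw next-iteration weights d_i = u_i^2 * 2 p_i (1 - p_i)."""
    uv = u.u_hat if isinstance(u, SnpEffectSet) else np.asarray(u, dtype=float)
    p = np.asarray(p, dtype=float)
    if uv.shape != p.shape:
        raise ValueError("effect and frequency vectors must have equal length")
    return uv**2 * 2.0 * p * (1.0 - p)


def normalize_weights(
    d_raw: np.ndarray,
    trace_target: float | None = None,
    iteration: int = 2,
    floor: float = 1e-8,
) -> SnpWeights:
    """Rescale weights to a constant trace (default: the marker count, i.e.
    trace(D at t=1)), preserving proportions.  All-zero input is floored to
    a uniform vector with a warning."""
    d = np.asarray(d_raw, dtype=float).copy()
    m = d.shape[0]
    target = float(trace_target) if trace_target is not None else float(m)
    if d.sum() <= 0:
        warnings.warn("all SNP weights zero; flooring to uniform", RuntimeWarning,
                      stacklevel=2)
        d[:] = 1.0
    d = np.maximum(d, floor)
    d *= target / d.sum()
    return SnpWeights(d=d, iteration=iteration)


@dataclass(frozen=True)
class WssgwasIteration:
    iteration: int
    weights: SnpWeights
    solution: MmeSolution
    effects: SnpEffectSet


@dataclass(frozen=True)
class WssgwasResult:
    iterations: list[WssgwasIteration]
    Z: np.ndarray = field(repr=False, default=None)
    lam: float = float("nan")
    freqs: np.ndarray = field(repr=False, default=None)
    md: MarkerData = field(repr=False, default=None)

    @property
    def final(self) -> WssgwasIteration:
        return self.iterations[-1]


def run_wssgwas(
    data: TraitDataset,
    md: MarkerData,
    ped: Pedigree,
    vc: VarianceComponents,
    cfg: WssgwasConfig = WssgwasConfig(),
    compute_pev: bool = False,
    F: np.ndarray | None = None,
) -> WssgwasResult:
    """Run the full re-weighting loop for ``cfg.n_iterations`` cycles.

    Each cycle builds the weighted G, solves the single-step MME for GEBVs,
    back-solves SNP effects against the unblended G (exact reconstruction),
    and updates the weights for the next cycle.  Iteration 1 (D = I) is
    plain single-step GBLUP.
    """
    md = md.sorted_by_map()
    missing = [s for s in md.sample_ids if s not in ped.index]
    if missing:
        raise KeyError(f"genotyped animals absent from pedigree: {missing[:5]}")
    Z, lam, p = gene_content_centered(md)
    Ainv = a_inverse(ped).values
    A22 = numerator_matrix(ped, subset=md.sample_ids).values
    A22inv = la.inv(A22)
    gidx = np.array([ped.index[s] for s in md.sample_ids], dtype=np.int64)

    weights = SnpWeights.identity(md.n_markers)
    out: list[WssgwasIteration] = []
    for t in range(1, cfg.n_iterations + 1):
        G = genomic_matrix(Z, weights, lam)
        Gb = blend(G, A22, tau=cfg.blend_tau)
        Ginv_b = la.inv(Gb)
        Hinv = h_inverse(Ainv, Ginv_b, A22inv, gidx)
        sol = solve_mme(data, vc, Hinv, ped_ids=ped.ids,
                        compute_pev=compute_pev, F=F)
        a_g = sol.a_hat[gidx]
        u, rank = _backsolve_minnorm(a_g, Z, weights.d, lam)
        if rank < min(len(a_g) - 1, md.n_markers):
            warnings.warn(
                f"weighted G has rank {rank} < {min(len(a_g) - 1, md.n_markers)}; "
                "GEBV reconstruction is restricted to its range",
                RuntimeWarning, stacklevel=2,
            )
        eff = SnpEffectSet(u_hat=u, iteration=t, gebv_g=a_g.copy())
        out.append(WssgwasIteration(iteration=t, weights=weights,
                                    solution=sol, effects=eff))
        if t < cfg.n_iterations:
            weights = normalize_weights(
                update_weights(eff, p), trace_target=md.n_markers,
                iteration=t + 1, floor=cfg.weight_floor,
            )
    return WssgwasResult(iterations=out, Z=Z, lam=lam, freqs=p, md=md)


def window_scan(
    u: SnpEffectSet | np.ndarray,
    Z: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    sigma_a2: float,
    window_bp: int = 520_000,
    ddof: int = 0,
) -> WindowVariance:
    """Sliding-window percentage of genetic variance explained.

    For each anchor SNP j the window is the run of consecutive SNPs on the
    same chromosome with position < pos_j + window_bp.  The window genetic
    value a_w = sum_j Z_j u_j across individuals gives
    pct = Var(a_w) / sigma_a2 * 100.
    """
    uv = u.u_hat if isinstance(u, SnpEffectSet) else np.asarray(u, dtype=float)
    pos = np.asarray(pos)
    chrom = np.asarray(chrom, dtype=object)
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    n_ind = Z.shape[0]
    rows = []
    for c in pd.unique(chrom):
        sel = np.where(chrom == c)[0]
        cp = pos[sel]
        if np.any(np.diff(cp) < 0):
            raise ValueError(f"markers on chromosome {c} are not position-sorted")
        # per-individual cumulative genetic value over the chromosome's SNPs
        contrib = Z[:, sel] * uv[sel]
        cum = np.concatenate([np.zeros((n_ind, 1)), np.cumsum(contrib, axis=1)], axis=1)
        ends = np.searchsorted(cp, cp + window_bp, side="left")
        for jj, j in enumerate(sel):
            k = ends[jj]
            a_w = cum[:, k] - cum[:, jj]
            var = float(np.var(a_w, ddof=ddof))
            rows.append((str(c), int(cp[jj]), int(cp[k - 1]), jj, int(k - jj),
                         100.0 * var / sigma_a2, int(sel[0] + jj), int(sel[0] + k - 1)))
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "anchor",
                                     "n_snp", "pct_var", "first_idx", "last_idx"])
    return WindowVariance(windows=df, sigma_a2=sigma_a2, window_bp=window_bp)


def significant_windows(
    wv: WindowVariance, threshold_pct: float = 1.56
) -> pd.DataFrame:
    """Anchors at or above the threshold, merged into regions.

    Overlapping significant windows on a chromosome collapse into one region
    reported as (chrom, start_bp, end_bp, max_pct, n_snp) with n_snp the
    number of distinct SNPs across the merged windows.
    """
    sig = wv.windows[wv.windows["pct_var"] >= threshold_pct]
    regions = []
    for c, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start_bp")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start_bp <= cur["end_bp"]:
                cur["end_bp"] = max(cur["end_bp"], row.end_bp)
                cur["max_pct"] = max(cur["max_pct"], row.pct_var)
                cur["last_idx"] = max(cur["last_idx"], row.last_idx)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": c, "start_bp": row.start_bp, "end_bp": row.end_bp,
                       "max_pct": row.pct_var, "first_idx": row.first_idx,
                       "last_idx": row.last_idx}
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(regions, columns=["chrom", "start_bp", "end_bp",
                                         "max_pct", "first_idx", "last_idx"])
    out["n_snp"] = (out["last_idx"] - out["first_idx"] + 1) if len(out) else pd.Series(dtype=int)
    return out[["chrom", "start_bp", "end_bp", "max_pct", "n_snp"]]


def genotype_class_means(
    data: TraitDataset, md: MarkerData, marker_id: str
) -> pd.DataFrame:
    """Mean trait value per genotype class (0/1/2) at one marker.

    Averages records of the samples in each class; classes with no records
    are omitted (not reported as zero).  The attribute
    ``df.attrs['hom_difference']`` holds mean(class 2) − mean(class 0) when
    both homozygote classes are present.
    """
    try:
        j = md.marker_ids.index(marker_id)
    except ValueError:
        raise KeyError(f"marker {marker_id!r} not present") from None
    calls = md.calls[:, j]
    cls_of = {s: calls[i] for i, s in enumerate(md.sample_ids)}
    rec = data.records
    classes = rec["animal_id"].astype(str).map(cls_of)
    keep = classes.notna()
    grouped = rec.loc[keep, "value"].groupby(classes[keep].astype(int))
    df = grouped.agg(n_records="size", mean="mean").reset_index(names="genotype")
    means = dict(zip(df["genotype"], df["mean"]))
    df.attrs["hom_difference"] = (
        means[2] - means[0] if 0 in means and 2 in means else float("nan")
    )
    return df


def _read_annotation(path) -> pd.DataFrame:
    """Gene intervals as 1-based half-open [start, end) rows:
    chrom, start, end, gene."""
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gtf")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "?")
                # GFF3 is 1-based inclusive
                rows.append((f[0], int(f[3]), int(f[4]) + 1, name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"],
                      dtype={0: str})
    # BED is 0-based half-open
    bed["start"] = bed["start"].astype(int) + 1
    bed["end"] = bed["end"].astype(int) + 1
    return bed


def annotate_windows(regions: pd.DataFrame, annotation_path) -> pd.DataFrame:
    """Attach overlapping gene names to each significant region.

    Regions are taken as 1-based half-open [start_bp, end_bp); genes merely
    abutting the region end are excluded.  Regions without genes get "-";
    a chromosome name present in regions but absent from the annotation is
    reported in ``df.attrs['unmatched_chroms']``.
    """
    ann = _read_annotation(annotation_path)
    ann_chroms = set(ann["chrom"].astype(str))
    out = regions.copy()
    genes_col = []
    unmatched = sorted(
        {str(c) for c in regions["chrom"]} - ann_chroms
    ) if len(regions) else []
    for row in regions.itertuples(index=False):
        sub = ann[ann["chrom"].astype(str) == str(row.chrom)]
        hit = sub[(sub["start"] < row.end_bp) & (row.start_bp < sub["end"])]
        genes_col.append(", ".join(hit["gene"]) if len(hit) else "-")
    out["genes"] = genes_col
    out.attrs["unmatched_chroms"] = unmatched
    return out
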