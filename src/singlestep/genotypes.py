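"""SNP genotype containers, quality control, and gene content.

Genotypes are stored as counted-allele dosages 0/1/2 (``NaN`` = missing).
QC mirrors a standard PLINK-style pipeline: unknown map position, sex
chromosome, call rate, minor allele frequency, and an exact
Hardy–Weinberg test, applied in that fixed order so removal counts are
reproducible.  Parent–offspring conflicts are scored as the opposing-
homozygote rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd

#: chromosome labels removed by the sex-chromosome rule (pig 19/20 aliases included)
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "MT", "M", "19", "20"})


@dataclass(frozen=True)
class MarkerData:
    """Samples × markers dosage matrix with its map.

    ``calls[i, j]`` counts copies of the per-marker counted allele in sample
    ``i`` (``NaN`` = missing).  ``chrom``/``pos`` give map coordinates;
    ``pos`` is -1 when unknown.  ``alleles[j]`` is the (counted, other) pair
    when known.
    """

    sample_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    alleles: tuple[tuple[str, str], ...] = field(default=(), repr=False)

    def __post_init__(self):
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("calls shape does not match sample/marker ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def freqs(self) -> np.ndarray:
        """Counted-allele frequency per marker from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def sorted_by_map(self) -> "MarkerData":
        """Markers reordered by (chromosome, position); chromosomes sorted
        numerically where possible."""

        def chrom_key(c: str):
            return (0, int(c)) if c.isdigit() else (1, c)

        order = sorted(
            range(self.n_markers), key=lambda j: (chrom_key(str(self.chrom[j])), self.pos[j])
        )
        return self.take_markers(np.asarray(order))

    def take_markers(self, idx: np.ndarray) -> "MarkerData":
        return replace(
            self,
            marker_ids=tuple(self.marker_ids[j] for j in idx),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            calls=self.calls[:, idx],
            alleles=tuple(self.alleles[j] for j in idx) if self.alleles else (),
        )

    def take_samples(self, ids: Sequence[str]) -> "MarkerData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"samples not present: {missing[:5]}")
        rows = np.array([index[s] for s in ids], dtype=np.int64)
        return replace(self, sample_ids=tuple(ids), calls=self.calls[rows])


@dataclass(frozen=True)
class QcConfig:
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_p_min: float = 1e-6
    drop_sex_chromosomes: bool = True
    drop_unknown_position: bool = True
    parentage_conflict_max: float = 0.10

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "hwe_p_min", "parentage_conflict_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-rule marker removal counts; reconciles exactly with dimensions."""

    n_markers_in: int = 0
    n_samples_in: int = 0
    removed_unknown_position: int = 0
    removed_sex_chromosome: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_markers_out: int = 0
    flagged_parentage: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            self.removed_unknown_position
            + self.removed_sex_chromosome
            + self.removed_call_rate
            + self.removed_maf
            + self.removed_hwe
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_markers_in", "n_samples_in", "removed_unknown_position",
            "removed_sex_chromosome", "removed_call_rate", "removed_maf",
            "removed_hwe", "n_markers_out")}
        d["flagged_parentage"] = [
            {"parent": p, "child": c, "rate": float(r)} for p, c, r in self.flagged_parentage
        ]
        return d


def read_plink_text(ped_path, map_path) -> MarkerData:
    """Read a PLINK .ped/.map text pair.

    The counted allele for each marker is the first non-missing allele
    encountered in file order; "0 0" genotypes become missing.  No filtering
    happens at read time.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "marker", "cm", "pos"], dtype={"chrom": str, "marker": str},
    )
    n_markers = len(mp)
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path} line {line_no}: expected {6 + 2 * n_markers} "
                    f"fields for {n_markers} markers, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    al = np.array(allele_rows, dtype="U8").reshape(len(sample_ids), n_markers, 2)
    calls = np.full((len(sample_ids), n_markers), np.nan)
    counted: list[tuple[str, str]] = []
    for j in range(n_markers):
        a = al[:, j, :]
        ok = (a[:, 0] != "0") & (a[:, 1] != "0")
        seen = a[ok]
        if seen.size == 0:
            counted.append(("?", "?"))
            continue
        ref = seen.ravel()[0]
        others = np.setdiff1d(seen.ravel(), [ref])
        counted.append((str(ref), str(others[0]) if others.size else str(ref)))
        calls[ok, j] = (a[ok] == ref).sum(axis=1)
    pos = mp["pos"].to_numpy(dtype=np.int64)
    return MarkerData(
        sample_ids=tuple(sample_ids),
        marker_ids=tuple(mp["marker"]),
        chrom=mp["chrom"].to_numpy(dtype=object),
        pos=pos,
        calls=calls,
        alleles=tuple(counted),
    )


def read_matrix_tsv(geno_path, map_path) -> MarkerData:
    """Read a samples × markers dosage TSV (values 0/1/2/NA) plus a map TSV
    with columns ``marker, chrom, pos``."""
    g = pd.read_csv(geno_path, sep="\t", index_col=0)
    mp = pd.read_csv(map_path, sep="\t", dtype={"marker": str, "chrom": str})
    if list(g.columns) != list(mp["marker"]):
        raise ValueError("genotype columns do not match map markers")
    calls = g.to_numpy(dtype=float)
    bad = ~(np.isnan(calls) | np.isin(calls, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype value {calls[i, j]!r} for sample "
            f"{g.index[i]!r}, marker {g.columns[j]!r}"
        )
    return MarkerData(
        sample_ids=tuple(str(s) for s in g.index),
        marker_ids=tuple(mp["marker"]),
        chrom=mp["chrom"].to_numpy(dtype=object),
        pos=mp["pos"].to_numpy(dtype=np.int64),
        calls=calls,
    )


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value (Wigginton/PLINK style).

    Sums the probabilities, conditional on allele counts, of all heterozygote
    counts no more probable than the observed one.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped samples")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)

    def logp(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return (
            h * np.log(2.0)
            + lgamma(n + 1) - lgamma(h + 1) - lgamma(rare_hom + 1) - lgamma(common_hom + 1)
        )

    logs = np.array([logp(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hets == n_het)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(md: MarkerData, cfg: QcConfig = QcConfig()) -> tuple[MarkerData, QcReport]:
    """Apply marker filters in fixed order: unknown position, sex chromosome,
    call rate, MAF, HWE.  Returns the surviving markers and an itemized report."""
    report = QcReport(n_markers_in=md.n_markers, n_samples_in=md.n_samples)
    keep = np.ones(md.n_markers, dtype=bool)

    if cfg.drop_unknown_position:
        bad = keep & (md.pos < 1)
        report.removed_unknown_position = int(bad.sum())
        keep &= ~bad
    if cfg.drop_sex_chromosomes:
        on_sex = np.array([str(c).upper() in SEX_CHROMOSOMES for c in md.chrom])
        bad = keep & on_sex
        report.removed_sex_chromosome = int(bad.sum())
        keep &= ~bad
    cr = md.call_rate()
    bad = keep & (cr < cfg.min_call_rate)
    report.removed_call_rate = int(bad.sum())
    keep &= ~bad
    p = md.freqs()
    with np.errstate(invalid="ignore"):
        maf = np.where(np.isnan(p), 0.0, np.minimum(p, 1.0 - p))
    bad = keep & (maf < cfg.min_maf)
    report.removed_maf = int(bad.sum())
    keep &= ~bad
    if cfg.hwe_p_min > 0:
        bad = np.zeros(md.n_markers, dtype=bool)
        for j in np.where(keep)[0]:
            col = md.calls[:, j]
            col = col[~np.isnan(col)]
            counts = [(col == g).sum() for g in (0.0, 1.0, 2.0)]
            if sum(counts) and hwe_exact_p(*counts) < cfg.hwe_p_min:
                bad[j] = True
        report.removed_hwe = int(bad.sum())
        keep &= ~bad

    out = md.take_markers(np.where(keep)[0])
    report.n_markers_out = out.n_markers
    return out, report


def parentage_conflict_rate(
    parent_calls: np.ndarray, child_calls: np.ndarray
) -> float:
    """Opposing-homozygote rate between a putative parent and child.

    (# markers with genotypes 0 and 2) / (# jointly non-missing markers).
    """
    p = np.asarray(parent_calls, dtype=float)
    c = np.asarray(child_calls, dtype=float)
    if p.shape != c.shape:
        raise ValueError("call vectors must have equal length")
    joint = ~np.isnan(p) & ~np.isnan(c)
    n_joint = int(joint.sum())
    if n_joint == 0:
        raise ValueError("no jointly non-missing markers")
    opposing = ((p == 0) & (c == 2)) | ((p == 2) & (c == 0))
    return float((opposing & joint).sum() / n_joint)


def flag_parentage_conflicts(md: MarkerData, ped, cfg: QcConfig) -> list[tuple[str, str, float]]:
    """Score every genotyped parent–child pair in ``ped`` and return those
    whose opposing-homozygote rate exceeds the threshold."""
    index = {s: i for i, s in enumerate(md.sample_ids)}
    flagged = []
    for child in md.sample_ids:
        if child not in ped.index:
            continue
        for parent in ped.parents_of(child):
            if parent is None or parent not in index:
                continue
            try:
                rate = parentage_conflict_rate(
                    md.calls[index[parent]], md.calls[index[child]]
                )
            except ValueError:
                continue
            if rate > cfg.parentage_conflict_max:
                flagged.append((parent, child, rate))
    return flagged


def gene_content_centered(
    md: MarkerData, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Allele-frequency-centered gene content Z and the scaling constant.

    Missing calls are imputed to their marker mean 2p before centering;
    ``lam = 1 / sum_i 2 p_i (1 - p_i)``, which is invariant to which allele
    is counted.  Returns ``(Z, lam, p)``.
    """
    p = md.freqs() if freqs is None else np.asarray(freqs, dtype=float)
    het = 2.0 * p * (1.0 - p)
    if np.any(het <= 0):
        j = int(np.argmin(het))
        raise ValueError(
            f"monomorphic marker {md.marker_ids[j]!r}; run QC before computing gene content"
        )
    calls = md.calls.copy()
    miss = np.isnan(calls)
    if miss.any():
        calls[miss] = np.broadcast_to(2.0 * p, calls.shape)[miss]
    Z = calls - 2.0 * p
    lam = 1.0 / float(het.sum())
    return Z, lam, p
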