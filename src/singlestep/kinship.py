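"""Genomic relationship matrix G and the single-step H inverse.

G = Z D Z' * lam follows the allele-frequency-scaled construction, with an
optional diagonal SNP-weight matrix D used by the weighted single-step
iterations.  H inverse combines the pedigree inverse with the genotyped-block
difference G⁻¹ − A22⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from singlestep.genotypes import MarkerData, gene_content_centered
from singlestep.pedigree import Pedigree, a_inverse, numerator_matrix


@dataclass(frozen=True)
class SnpWeights:
    """Diagonal SNP-variance weights D at a given iteration (t=1: D=I)."""

    d: np.ndarray
    iteration: int = 1

    def __post_init__(self):
        if np.any(self.d < 0):
            raise ValueError("SNP weights must be non-negative")

    @classmethod
    def identity(cls, n_markers: int) -> "SnpWeights":
        return cls(d=np.ones(n_markers), iteration=1)


def genomic_matrix(Z: np.ndarray, weights: SnpWeights | np.ndarray, lam: float) -> np.ndarray:
    """G = Z diag(d) Z' * lam on centered gene content."""
    d = weights.d if isinstance(weights, SnpWeights) else np.asarray(weights, dtype=float)
    if Z.shape[1] != d.shape[0]:
        raise ValueError(f"Z has {Z.shape[1]} markers but weights has {d.shape[0]}")
    G = (Z * d) @ Z.T * lam
    return 0.5 * (G + G.T)


def blend(G: np.ndarray, A22: np.ndarray, tau: float = 0.95) -> np.ndarray:
    """Invertibility blend G* = tau G + (1 - tau) A22."""
    if G.shape != A22.shape:
        raise ValueError("G and A22 must be conformable and identically ordered")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    return tau * G + (1.0 - tau) * A22


def h_inverse(
    Ainv: sp.spmatrix,
    Ginv: np.ndarray,
    A22inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """H⁻¹ = A⁻¹ plus (G⁻¹ − A22⁻¹) scattered onto the genotyped block."""
    n = Ainv.shape[0]
    idx = np.asarray(genotyped_index, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError("genotyped_index out of range")
    if Ginv.shape != A22inv.shape or Ginv.shape[0] != idx.size:
        raise ValueError("Ginv/A22inv must match the genotyped index length")
    if idx.size == 0:
        return sp.csr_matrix(Ainv)
    diff = Ginv - A22inv
    rows = np.repeat(idx, idx.size)
    cols = np.tile(idx, idx.size)
    block = sp.coo_matrix((diff.ravel(), (rows, cols)), shape=(n, n))
    return (sp.csr_matrix(Ainv) + block.tocsr()).tocsr()


@dataclass(frozen=True)
class KinshipSet:
    """All relationship structures needed by one single-step evaluation."""

    ped_ids: tuple[str, ...]
    genotyped_ids: tuple[str, ...]
    genotyped_index: np.ndarray
    Ainv: sp.csr_matrix
    A22: np.ndarray
    A22inv: np.ndarray
    G: np.ndarray
    Ginv: np.ndarray
    Hinv: sp.csr_matrix


def build_kinship(
    ped: Pedigree,
    md: MarkerData,
    weights: SnpWeights | None = None,
    tau: float = 0.95,
    use_inbreeding: bool = True,
) -> KinshipSet:
    """Assemble A⁻¹, A22, (blended) G, and H⁻¹ for one evaluation.

    Genotyped samples must all appear in the pedigree; ``tau`` < 1 blends G
    with A22 to guarantee invertibility.
    """
    missing = [s for s in md.sample_ids if s not in ped.index]
    if missing:
        raise KeyError(f"genotyped animals absent from pedigree: {missing[:5]}")
    weights = weights or SnpWeights.identity(md.n_markers)
    Ainv = a_inverse(ped, use_inbreeding=use_inbreeding).values
    A22 = numerator_matrix(ped, subset=md.sample_ids).values
    Z, lam, _ = gene_content_centered(md)
    G = blend(genomic_matrix(Z, weights, lam), A22, tau=tau)
    Ginv = la.inv(G)
    A22inv = la.inv(A22)
    gidx = np.array([ped.index[s] for s in md.sample_ids], dtype=np.int64)
    Hinv = h_inverse(sp.csr_matrix(Ainv), Ginv, A22inv, gidx)
    return KinshipSet(
        ped_ids=ped.ids,
        genotyped_ids=md.sample_ids,
        genotyped_index=gidx,
        Ainv=sp.csr_matrix(Ainv),
        A22=A22,
        A22inv=A22inv,
        G=G,
        Ginv=Ginv,
        Hinv=Hinv,
    )
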