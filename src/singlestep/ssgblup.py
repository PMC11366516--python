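"""Breeding-value prediction by the mixed-model equations.

Solves Henderson's MME for pedigree BLUP (K⁻¹ = A⁻¹), single-step GBLUP
(K⁻¹ = H⁻¹), or the weighted variants, and reports per-animal prediction-
error variances and accuracies r = sqrt(1 − PEV / ((1 + F) sigma_a2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from singlestep.genotypes import MarkerData
from singlestep.pedigree import Pedigree, RelationshipMatrix, a_inverse, inbreeding
from singlestep.reml import (
    TraitDataset,
    VarianceComponents,
    _factor_and_solve,
    _kinv_dense,
    _pev_additive,
    assemble_design,
)


@dataclass(frozen=True)
class MmeSolution:
    """Solutions of the mixed-model equations for one trait/K structure."""

    ped_ids: tuple[str, ...]
    b_hat: np.ndarray
    a_hat: np.ndarray
    pe_hat: np.ndarray
    pe_ids: tuple[str, ...]
    pev: np.ndarray | None = None
    accuracy: np.ndarray | None = None
    residual_rel_norm: float = 0.0
    flags: tuple = ()

    def ebv(self) -> pd.Series:
        return pd.Series(self.a_hat, index=list(self.ped_ids), name="ebv")

    def mean_accuracy(self, animals=None) -> float:
        """Mean PEV-based accuracy, by default over PE (recorded) animals."""
        if self.accuracy is None:
            raise ValueError("solution was computed without PEV/accuracy")
        if animals is None:
            animals = self.pe_ids
        index = {a: i for i, a in enumerate(self.ped_ids)}
        return float(np.mean([self.accuracy[index[a]] for a in animals]))


def solve_mme(
    data: TraitDataset,
    vc: VarianceComponents,
    Kinv,
    ped_ids=None,
    include_pe: bool = True,
    compute_pev: bool = True,
    F: np.ndarray | None = None,
) -> MmeSolution:
    """Solve Henderson's MME at the given variance components.

    ``Kinv`` is the (sparse or dense) inverse relationship matrix over all
    pedigree animals.  With ``compute_pev`` the additive block of the
    coefficient-matrix inverse yields PEV and accuracies (``F`` supplies
    inbreeding coefficients for the accuracy denominator; zero if omitted).
    """
    if isinstance(Kinv, RelationshipMatrix) and ped_ids is None:
        ped_ids = Kinv.ids
    if ped_ids is None:
        raise ValueError("ped_ids required when Kinv carries no ids")
    if vc.sigma_e2 <= 0 or vc.sigma_a2 <= 0:
        raise ValueError("residual and additive variances must be positive")
    des = assemble_design(data, ped_ids, include_pe=include_pe)
    Kd = _kinv_dense(Kinv, ped_ids)
    theta = (vc.sigma_a2, vc.sigma_pe2 if include_pe else 0.0, vc.sigma_e2)
    fac = _factor_and_solve(des, Kd, theta)
    sa = slice(des.p, des.p + des.q)
    sol = fac.sol
    # verify the solve: residual of the full MME system, block by block
    a_hat = sol[sa]
    r_parts = [-des.X.T @ fac.e_hat,
               -des.Z.T @ fac.e_hat + (theta[2] / theta[0]) * (Kd @ a_hat)]
    if des.qpe:
        pe_hat = sol[des.p + des.q:]
        r_parts.append(-des.W.T @ fac.e_hat + (theta[2] / theta[1]) * pe_hat)
    resid = np.concatenate(r_parts)
    rel = float(la.norm(resid) / max(la.norm(des.rhs_full), 1e-300))

    pev = acc = None
    flags: list[str] = []
    if compute_pev:
        pev = _pev_additive(des, fac, theta[2])
        Fv = np.zeros(des.q) if F is None else np.asarray(F, dtype=float)
        acc, n_clip = ebv_accuracy(pev, Fv, vc.sigma_a2, return_clipped=True)
        if n_clip:
            flags.append("accuracy_clipped")
    return MmeSolution(
        ped_ids=tuple(ped_ids),
        b_hat=sol[: des.p].copy(),
        a_hat=sol[sa].copy(),
        pe_hat=sol[des.p + des.q:].copy() if des.qpe else np.zeros(0),
        pe_ids=des.pe_ids,
        pev=pev,
        accuracy=acc,
        residual_rel_norm=rel,
        flags=tuple(flags),
    )


def ebv_accuracy(
    pev: np.ndarray,
    F: np.ndarray,
    sigma_a2: float,
    return_clipped: bool = False,
):
    """Per-animal accuracy r_i = sqrt(1 − PEV_i / ((1 + F_i) sigma_a2)).

    PEV above the theoretical ceiling (1 + F) sigma_a2 is clipped to it with
    a warning (it can exceed by rounding at low information).
    """
    pev = np.asarray(pev, dtype=float)
    ceiling = (1.0 + np.asarray(F, dtype=float)) * sigma_a2
    over = pev > ceiling * (1 + 1e-8)
    if over.any():
        warnings.warn(
            f"{int(over.sum())} PEV values exceed (1+F)*sigma_a2; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.sqrt(np.clip(1.0 - pev / ceiling, 0.0, 1.0))
    if return_clipped:
        return r, int(over.sum())
    return r


@dataclass(frozen=True)
class MethodComparison:
    """Mean accuracies per method, Table-2 style; truth correlations when a
    simulated truth is available."""

    table: pd.DataFrame
    solutions: dict = field(repr=False, default_factory=dict)


def compare_methods(
    data: TraitDataset,
    md: MarkerData,
    ped: Pedigree,
    vc: VarianceComponents,
    n_iterations: int = 3,
    tau: float = 0.95,
    true_bv: pd.Series | None = None,
    accuracy_animals: str = "genotyped",
) -> MethodComparison:
    """Compare PBLUP against weighted single-step GBLUP across iterations.

    Runs pedigree BLUP and the SNP-reweighting loop (iteration 1 = plain
    ssGBLUP with D = I), reporting the mean PEV accuracy and, when
    ``true_bv`` is given, the correlation between predicted and true
    breeding values over the genotyped (or recorded) animals.
    """
    from singlestep.wssgwas import WssgwasConfig, run_wssgwas

    Fv = inbreeding(ped)
    Ainv = a_inverse(ped)
    pb = solve_mme(data, vc, Ainv, F=Fv)
    if accuracy_animals == "genotyped" and md.n_samples:
        eval_ids = [s for s in md.sample_ids if s in ped.index]
    else:
        eval_ids = list(pb.pe_ids)

    def truth_corr(sol: MmeSolution) -> float:
        if true_bv is None:
            return float("nan")
        ebv = sol.ebv().loc[eval_ids]
        return float(np.corrcoef(ebv.to_numpy(), true_bv.loc[eval_ids].to_numpy())[0, 1])

    rows = [{
        "method": "PBLUP",
        "mean_accuracy": pb.mean_accuracy(eval_ids),
        "truth_correlation": truth_corr(pb),
    }]
    solutions: dict = {"PBLUP": pb}

    if md.n_samples:
        cfg = WssgwasConfig(n_iterations=n_iterations, blend_tau=tau)
        result = run_wssgwas(data, md, ped, vc, cfg, compute_pev=True, F=Fv)
        for it in result.iterations:
            name = f"WssGBLUP_iter{it.iteration}"
            rows.append({
                "method": name,
                "mean_accuracy": it.solution.mean_accuracy(eval_ids),
                "truth_correlation": truth_corr(it.solution),
            })
            solutions[name] = it.solution
    table = pd.DataFrame(rows)
    return MethodComparison(table=table, solutions=solutions)
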