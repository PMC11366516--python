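"""Variance components for the single-trait repeatability animal model.

The model is y = Xb + Za + Wpe + e with additive genetic effects a
(Var(a) = K sigma_a2 for a pedigree, genomic, or combined K), a permanent-
environment effect per animal with records (Var(pe) = I sigma_pe2), and iid
residuals.  Components are estimated by average-information REML: every
round computes both the EM update and the AI (Newton-type) update from the
mixed-model equations; the AI step is taken whenever it stays inside the
parameter space, otherwise the round falls back to EM, whose steps never
decrease the restricted likelihood.

Because every record carries exactly one animal and one PE level, the PE
equations are diagonal after ordering and are absorbed analytically before
factorization; solutions, traces, and the restricted likelihood are exact,
only the factorized system shrinks to the fixed + additive equations.

Standard errors come from the inverse AI matrix at convergence, and the
heritability h2 = sigma_a2 / (sigma_a2 + sigma_pe2 + sigma_e2) gets a
delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from singlestep.pedigree import RelationshipMatrix


@dataclass(frozen=True)
class TraitDataset:
    """Repeated-record phenotypes: one row per farrowing/record.

    ``records`` columns: ``animal_id`` (string), ``parity`` and
    ``year_season`` (categorical levels), ``value`` (trait measurement).
    """

    records: pd.DataFrame

    def __post_init__(self):
        required = {"animal_id", "parity", "year_season", "value"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def animals(self) -> list[str]:
        """Animals with records, in first-appearance order (the PE levels)."""
        return list(dict.fromkeys(self.records["animal_id"].astype(str)))


def read_phenotypes(path) -> TraitDataset:
    """Read a phenotype CSV with columns ``animal,parity,year_season,value``."""
    df = pd.read_csv(path, dtype={"animal": str})
    df = df.rename(columns={"animal": "animal_id"})
    return TraitDataset(records=df[["animal_id", "parity", "year_season", "value"]])


@dataclass(frozen=True)
class VarianceComponents:
    sigma_a2: float
    sigma_pe2: float
    sigma_e2: float
    se: dict = field(default_factory=dict)
    h2: float = float("nan")
    h2_se: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    loglik: float = float("nan")
    flags: tuple = ()
    history: tuple = ()  # restricted log-likelihood per round

    def total(self) -> float:
        return self.sigma_a2 + self.sigma_pe2 + self.sigma_e2


def heritability(vc, sigma_pe2=None, sigma_e2=None) -> float:
    """h2 = sigma_a2 / (sigma_a2 + sigma_pe2 + sigma_e2).

    Accepts either a :class:`VarianceComponents` or the three variances.
    """
    if isinstance(vc, VarianceComponents):
        a, p, e = vc.sigma_a2, vc.sigma_pe2, vc.sigma_e2
    else:
        a, p, e = float(vc), float(sigma_pe2), float(sigma_e2)
    if min(a, p, e) < 0:
        raise ValueError("variance components must be non-negative")
    tot = a + p + e
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return a / tot


class Design(NamedTuple):
    """Assembled design for one trait.

    ``M0`` is the fixed + additive part of the MME coefficient matrix
    without variance-ratio terms; the PE block is carried as its diagonal
    record counts plus the couplings ``XtW`` and the one animal per PE
    level (``a_of_pe``).
    """

    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    W: sp.csr_matrix | None
    pe_ids: tuple[str, ...]
    M0: np.ndarray
    XtW: np.ndarray | None
    pe_counts: np.ndarray | None
    a_of_pe: np.ndarray | None
    rhs_full: np.ndarray
    n: int
    p: int
    q: int
    qpe: int


def assemble_design(
    data: TraitDataset, ped_ids: Sequence[str], include_pe: bool = True
) -> Design:
    """Build y, X, Z, W and the constant crossproduct blocks.

    Fixed effects are an intercept plus parity and year-season dummies with
    the first level dropped; any remaining redundant columns are pruned by
    pivoted QR so X has full column rank.
    """
    rec = data.records
    ped_index = {a: i for i, a in enumerate(ped_ids)}
    missing = sorted(set(rec["animal_id"].astype(str)) - set(ped_index))
    if missing:
        raise KeyError(f"record animals absent from pedigree: {missing[:5]}")
    y = rec["value"].to_numpy(dtype=float)
    n = len(y)

    cols = [np.ones((n, 1))]
    for f in ("parity", "year_season"):
        dummies = pd.get_dummies(rec[f].astype("category"), drop_first=True)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy(dtype=float))
    X = np.hstack(cols)
    # prune redundant columns (confounded levels) via pivoted QR
    R, piv = la.qr(X, mode="r", pivoting=True)
    r_diag = np.abs(np.diag(R))
    rank = int((r_diag > r_diag[0] * 1e-10).sum()) if r_diag.size else 0
    if rank < X.shape[1]:
        X = X[:, np.sort(piv[:rank])]
    p = X.shape[1]

    q = len(ped_ids)
    a_idx = rec["animal_id"].astype(str).map(ped_index).to_numpy()
    Z = sp.coo_matrix((np.ones(n), (np.arange(n), a_idx)), shape=(n, q)).tocsr()

    M0 = np.zeros((p + q, p + q))
    sa = slice(p, p + q)
    M0[:p, :p] = X.T @ X
    XtZ = X.T @ Z
    M0[:p, sa] = XtZ
    M0[sa, :p] = XtZ.T
    M0[sa, sa][np.diag_indices(q)] = np.bincount(a_idx, minlength=q)
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    if include_pe:
        pe_ids = tuple(data.animals)
        pe_index = {a: i for i, a in enumerate(pe_ids)}
        pe_idx = rec["animal_id"].astype(str).map(pe_index).to_numpy()
        qpe = len(pe_ids)
        W = sp.coo_matrix(
            (np.ones(n), (np.arange(n), pe_idx)), shape=(n, qpe)
        ).tocsr()
        XtW = np.asarray(X.T @ W.toarray()) if qpe else np.zeros((p, 0))
        pe_counts = np.asarray(W.sum(axis=0)).ravel()
        a_of_pe = np.array([ped_index[a] for a in pe_ids], dtype=np.int64)
        rhs = np.concatenate([rhs, W.T @ y])
    else:
        W, pe_ids, qpe = None, (), 0
        XtW = pe_counts = a_of_pe = None
    return Design(y=y, X=X, Z=Z, W=W, pe_ids=pe_ids, M0=M0, XtW=XtW,
                  pe_counts=pe_counts, a_of_pe=a_of_pe, rhs_full=rhs,
                  n=n, p=p, q=q, qpe=qpe)


def _kinv_dense(Kinv, ped_ids):
    if isinstance(Kinv, RelationshipMatrix):
        if tuple(Kinv.ids) != tuple(ped_ids):
            raise ValueError("Kinv ids do not match the pedigree ordering")
        Kinv = Kinv.values
    return Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv, dtype=float)


class _MmeFactor(NamedTuple):
    sol: np.ndarray      # full solutions (b, a, pe)
    e_hat: np.ndarray
    logdet: float        # log-determinant of the FULL coefficient matrix
    cho: tuple           # Cholesky of the absorbed (fixed+additive) system
    Dpe: np.ndarray | None
    ytPy: float          # y'y - sol' rhs  (= y' e_hat)


def _solve_full(des: Design, cho, Dpe, rhs_full: np.ndarray) -> np.ndarray:
    """Solve the full MME via the PE-absorbed factor; rhs may be 1-D or 2-D
    (equations on axis 0)."""
    one_d = rhs_full.ndim == 1
    R = rhs_full[:, None] if one_d else rhs_full
    nb = des.p + des.q
    rb = R[:nb].copy()
    if des.qpe:
        wpart = R[nb:] / Dpe[:, None]
        rb[: des.p] -= des.XtW @ wpart
        rb[des.p + des.a_of_pe] -= des.pe_counts[:, None] * wpart
    sol_ba = la.cho_solve(cho, rb, check_finite=False)
    if des.qpe:
        pe = (
            R[nb:]
            - des.XtW.T @ sol_ba[: des.p]
            - des.pe_counts[:, None] * sol_ba[des.p + des.a_of_pe]
        ) / Dpe[:, None]
        sol = np.vstack([sol_ba, pe])
    else:
        sol = sol_ba
    return sol[:, 0] if one_d else sol


def _factor_and_solve(des: Design, Kd: np.ndarray, theta) -> _MmeFactor:
    sig_a, sig_pe, sig_e = theta
    sa = slice(des.p, des.p + des.q)
    M = des.M0.copy()
    M[sa, sa] += Kd * (sig_e / sig_a)
    Dpe = None
    logdet_pe = 0.0
    if des.qpe:
        Dpe = des.pe_counts + sig_e / sig_pe
        logdet_pe = float(np.sum(np.log(Dpe)))
        # absorb the PE equations: M -= U D^-1 U' with U = [X'W; Z'W]
        Wd = des.XtW / Dpe
        M[: des.p, : des.p] -= Wd @ des.XtW.T
        cross = Wd * des.pe_counts
        acols = des.p + des.a_of_pe
        M[np.ix_(range(des.p), acols)] -= cross
        M[np.ix_(acols, range(des.p))] -= cross.T
        M[acols, acols] -= des.pe_counts**2 / Dpe
    cho = la.cho_factor(M, lower=True, overwrite_a=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0])))) + logdet_pe
    sol = _solve_full(des, cho, Dpe, des.rhs_full)
    fit = des.X @ sol[: des.p] + des.Z @ sol[sa]
    if des.qpe:
        fit = fit + des.W @ sol[des.p + des.q:]
    e_hat = des.y - fit
    ytPy = float(des.y @ des.y - sol @ des.rhs_full)
    return _MmeFactor(sol=sol, e_hat=e_hat, logdet=logdet, cho=cho, Dpe=Dpe,
                      ytPy=ytPy)


def _restricted_ll(des: Design, fac: _MmeFactor, theta) -> float:
    sig_a, sig_pe, sig_e = theta
    ll = -0.5 * (
        (des.n - des.p - des.q - des.qpe) * np.log(sig_e)
        + des.q * np.log(sig_a)
        + (des.qpe * np.log(sig_pe) if des.qpe else 0.0)
        + fac.logdet
        + fac.ytPy / sig_e
    )
    return float(ll)


def _inverse_blocks(des: Design, fac: _MmeFactor, Kd: np.ndarray):
    """tr(K⁻¹ C_aa) and tr(C_pepe) from the absorbed factor.

    C_aa is the additive block of the absorbed inverse (equal to the full-
    system block by the Schur identity); the PE block of the full inverse is
    D⁻¹ + D⁻¹ U' C U D⁻¹ and only its trace is needed.  Destroys the
    Cholesky factor.
    """
    Cinv, info = la.lapack.dpotri(fac.cho[0], lower=True)
    if info != 0:
        raise la.LinAlgError("dpotri failed on the MME factor")
    Cl = np.tril(Cinv)
    Cfull = Cl + Cl.T - np.diag(np.diag(Cl))
    sa = slice(des.p, des.p + des.q)
    tr_KC = float(np.sum(Kd * Cfull[sa, sa]))
    tr_Cpe = 0.0
    if des.qpe:
        acols = des.p + des.a_of_pe
        Cbb = Cfull[: des.p, : des.p]
        t1 = np.einsum("ik,ij,jk->k", des.XtW, Cbb, des.XtW)
        t2 = 2.0 * des.pe_counts * np.einsum(
            "ik,ik->k", des.XtW, Cfull[: des.p][:, acols]
        )
        t3 = des.pe_counts**2 * Cfull[acols, acols]
        tr_Cpe = float(np.sum(1.0 / fac.Dpe + (t1 + t2 + t3) / fac.Dpe**2))
    return tr_KC, tr_Cpe


def _pev_additive(des: Design, fac: _MmeFactor, sigma_e2: float) -> np.ndarray:
    """Prediction-error variance of each additive effect (diagonal of the
    additive inverse block times sigma_e2).  Destroys the Cholesky factor."""
    Cinv, info = la.lapack.dpotri(fac.cho[0], lower=True)
    if info != 0:
        raise la.LinAlgError("dpotri failed on the MME factor")
    return np.diag(Cinv[des.p:, des.p:]).copy() * sigma_e2


def profile_loglik(
    data: TraitDataset,
    Kinv,
    components,
    ped_ids: Sequence[str] | None = None,
    include_pe: bool = True,
) -> float:
    """Restricted log-likelihood at the given components, up to a constant.

    The constant omits log|K| and the 2*pi term, both invariant in the
    components, so likelihood *differences* are exact.
    ``components`` is (sigma_a2, sigma_pe2, sigma_e2).
    """
    if isinstance(Kinv, RelationshipMatrix) and ped_ids is None:
        ped_ids = Kinv.ids
    if ped_ids is None:
        raise ValueError("ped_ids required when Kinv carries no ids")
    des = assemble_design(data, ped_ids, include_pe=include_pe)
    Kd = _kinv_dense(Kinv, ped_ids)
    theta = tuple(float(t) for t in components)
    if not include_pe:
        theta = (theta[0], 0.0, theta[2])
    if theta[0] <= 0 or theta[2] <= 0 or (include_pe and theta[1] <= 0):
        raise ValueError("variance components must be positive")
    fac = _factor_and_solve(des, Kd, theta)
    return _restricted_ll(des, fac, theta)


def fit_reml(
    data: TraitDataset,
    Kinv,
    ped_ids: Sequence[str] | None = None,
    include_pe: bool = True,
    method: str = "ai",
    start: tuple | None = None,
    tol: float = 1e-8,
    max_rounds: int = 200,
) -> VarianceComponents:
    """AI-REML estimates of (sigma_a2, sigma_pe2, sigma_e2).

    ``Kinv`` is the inverse relationship matrix over all pedigree animals
    (A⁻¹ for pedigree BLUP, H⁻¹ for single-step); as a
    :class:`~singlestep.pedigree.RelationshipMatrix` it supplies the animal
    ordering, otherwise pass ``ped_ids``.  ``method="em"`` forces pure EM
    rounds (monotone in the restricted likelihood); the default takes AI
    steps with EM fallback.  Convergence: max relative component change
    below ``tol`` or ``max_rounds`` rounds (then flagged).
    """
    if isinstance(Kinv, RelationshipMatrix) and ped_ids is None:
        ped_ids = Kinv.ids
    if ped_ids is None:
        raise ValueError("ped_ids required when Kinv carries no ids")
    des = assemble_design(data, ped_ids, include_pe=include_pe)
    Kd = _kinv_dense(Kinv, ped_ids)
    vary = float(np.var(des.y))
    floor = max(vary, 1.0) * 1e-10
    flags: list[str] = []
    if vary <= 0:
        flags.append("degenerate_response")
        return VarianceComponents(
            sigma_a2=floor, sigma_pe2=floor if include_pe else 0.0,
            sigma_e2=floor, converged=False, flags=tuple(flags))

    if start is None:
        theta = np.array([0.2 * vary, 0.2 * vary if include_pe else 0.0, 0.6 * vary])
    else:
        theta = np.array(start, dtype=float)
    active = [0, 2] if not include_pe else [0, 1, 2]
    theta[active] = np.maximum(theta[active], floor)

    sa = slice(des.p, des.p + des.q)
    spe = slice(des.p + des.q, des.p + des.q + des.qpe)
    ll_prev = -np.inf
    em_prev: np.ndarray | None = None
    ai_inv = None
    n_iter = 0
    converged = False
    last_step_ai = False
    ll = np.nan
    history: list[float] = []

    for n_iter in range(1, max_rounds + 1):
        fac = _factor_and_solve(des, Kd, theta)
        ll = _restricted_ll(des, fac, theta)
        history.append(ll)
        if last_step_ai and ll < ll_prev - 1e-8 and em_prev is not None:
            # AI overshot: rewind and take the EM step from the previous round
            theta = em_prev.copy()
            last_step_ai = False
            continue
        ll_prev = ll

        a_hat = fac.sol[sa]
        pe_hat = fac.sol[spe] if des.qpe else np.zeros(0)
        # AI working vectors; solve against the factor before dpotri eats it
        f_cols = [des.Z @ (a_hat / theta[0]), fac.e_hat / theta[2]]
        if des.qpe:
            f_cols.insert(1, des.W @ (pe_hat / theta[1]))
        Fm = np.column_stack(f_cols)
        Rhs = np.vstack([des.X.T @ Fm, des.Z.T @ Fm])
        if des.qpe:
            Rhs = np.vstack([Rhs, des.W.T @ Fm])
        Sol = _solve_full(des, fac.cho, fac.Dpe, Rhs)
        PF = Fm - (des.X @ Sol[: des.p] + des.Z @ Sol[sa])
        if des.qpe:
            PF = PF - des.W @ Sol[spe]
        PF /= theta[2]
        AI = 0.5 * (Fm.T @ PF)
        AI = 0.5 * (AI + AI.T)

        tr_KC, tr_Cpe = _inverse_blocks(des, fac, Kd)

        aKa = float(a_hat @ (Kd @ a_hat))
        ee = float(fac.e_hat @ fac.e_hat)
        yte = fac.ytPy

        em = theta.copy()
        em[0] = (aKa + theta[2] * tr_KC) / des.q
        if des.qpe:
            em[1] = (float(pe_hat @ pe_hat) + theta[2] * tr_Cpe) / des.qpe
        em[2] = yte / (des.n - des.p)
        em[active] = np.maximum(em[active], floor)

        # gradient of the restricted log-likelihood
        g_a = -0.5 * (des.q / theta[0] - (aKa + theta[2] * tr_KC) / theta[0] ** 2)
        tr_PZKZ = des.q / theta[0] - theta[2] * tr_KC / theta[0] ** 2
        grads = [g_a]
        tr_PWW = 0.0
        if des.qpe:
            pp = float(pe_hat @ pe_hat)
            g_pe = -0.5 * (des.qpe / theta[1] - (pp + theta[2] * tr_Cpe) / theta[1] ** 2)
            tr_PWW = des.qpe / theta[1] - theta[2] * tr_Cpe / theta[1] ** 2
            grads.append(g_pe)
        tr_P = (des.n - des.p - theta[0] * tr_PZKZ - theta[1] * tr_PWW) / theta[2]
        g_e = -0.5 * (tr_P - ee / theta[2] ** 2)
        grads.append(g_e)
        g = np.array(grads)

        theta_prev = theta.copy()
        em_prev = em.copy()
        step_ai = False
        if method == "ai":
            try:
                delta = la.solve(AI, g, assume_a="sym")
                cand = theta[active] + delta
                if np.all(cand > floor):
                    new = theta.copy()
                    new[active] = cand
                    theta = new
                    step_ai = True
            except la.LinAlgError:
                pass
        if not step_ai:
            theta = em.copy()
        last_step_ai = step_ai
        try:
            ai_inv = la.inv(AI)
        except la.LinAlgError:
            ai_inv = None

        rel = np.max(
            np.abs(theta[active] - theta_prev[active])
            / np.maximum(theta_prev[active], floor)
        )
        if rel < tol:
            converged = True
            break

    if not converged:
        flags.append("non_convergence")
    se: dict[str, float] = {}
    h2_se = float("nan")
    if ai_inv is None:
        flags.append("flat_likelihood")
    names = ["sigma_a2", "sigma_pe2", "sigma_e2"] if des.qpe else ["sigma_a2", "sigma_e2"]
    if ai_inv is not None:
        eig = la.eigvalsh(0.5 * (ai_inv + ai_inv.T))
        if np.max(eig) > 0 and (
            np.min(eig) < 0 or np.max(eig) / max(np.min(eig), 1e-300) > 1e10
        ):
            flags.append("flat_likelihood")
        diag = np.clip(np.diag(ai_inv), 0.0, np.inf)
        se = {nm: float(np.sqrt(v)) for nm, v in zip(names, diag)}
        # delta method for h2 = s_a / S
        full = theta if des.qpe else np.array([theta[0], theta[2]])
        S = float(full.sum())
        grad_h = np.full(len(full), -theta[0] / S**2)
        grad_h[0] += 1.0 / S
        var_h2 = float(grad_h @ ai_inv @ grad_h)
        h2_se = float(np.sqrt(max(var_h2, 0.0)))

    h2 = heritability(theta[0], theta[1], theta[2])
    return VarianceComponents(
        sigma_a2=float(theta[0]),
        sigma_pe2=float(theta[1]),
        sigma_e2=float(theta[2]),
        se=se,
        h2=h2,
        h2_se=h2_se,
        converged=converged,
        n_iter=n_iter,
        loglik=float(ll),
        flags=tuple(flags),
        history=tuple(history),
    )
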