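"""Multi-trait BLUP / ssGBLUP with known variance components.

The mixed-model equations for the three-trait model (one overall mean per
trait, per-trait missing records, diagonal residual covariance) are solved
either densely (small problems, used as the reference path in tests) or by
Jacobi-preconditioned conjugate gradients on a matrix-free operator.  The
genetic covariance structure is G0 (x) K with K = A (pedigree BLUP) or H
(single step); K^-1 is applied as sparse A^-1 plus a dense correction
(G^-1 - A22^-1) on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .inheritance import PedigreeTable
from .kinship import (
    G_RIDGE,
    a_inverse,
    a_submatrix,
    build_G,
    diag_cor_G_A22,
    inbreeding_meuwissen_luo,
)
from .traits import INDEX_WEIGHTS

__all__ = [
    "MMEProblem",
    "EBVTable",
    "DenseKinshipOp",
    "PedigreeKinshipOp",
    "SingleStepKinshipOp",
    "pedigree_kinship",
    "single_step_kinship",
    "solve_mme",
    "selection_index",
    "accuracy",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        super().__init__(f"MME solver did not converge in {iterations} iterations (residual {residual:.3e})")
        self.residual = residual
        self.iterations = iterations


class DenseKinshipOp:
    """Explicit relationship matrix (small problems / tests)."""

    def __init__(self, k: np.ndarray):
        k = np.asarray(k, dtype=float)
        self.n = k.shape[0]
        self._kinv = np.linalg.inv(k)

    def inv_apply(self, v):
        return self._kinv @ v

    def inv_diag(self):
        return np.diag(self._kinv).copy()

    def inv_dense(self):
        return self._kinv


class PedigreeKinshipOp:
    """K = A applied through its sparse inverse."""

    def __init__(self, a_inv: sp.spmatrix):
        self.a_inv = a_inv.tocsr()
        self.n = a_inv.shape[0]

    def inv_apply(self, v):
        return self.a_inv @ v

    def inv_diag(self):
        return self.a_inv.diagonal()

    def inv_dense(self):
        return self.a_inv.toarray()


class SingleStepKinshipOp:
    """K = H: sparse A^-1 plus dense (G^-1 - A22^-1) on the genotyped block."""

    def __init__(self, a_inv: sp.spmatrix, genotyped_rows: np.ndarray, correction: np.ndarray, diagnostics: dict | None = None):
        self.a_inv = a_inv.tocsr()
        self.n = a_inv.shape[0]
        self.rows = np.asarray(genotyped_rows, dtype=np.intp)
        self.correction = np.asarray(correction, dtype=float)
        self.diagnostics = diagnostics or {}

    def inv_apply(self, v):
        out = self.a_inv @ v
        if self.rows.size:
            out[self.rows] += self.correction @ v[self.rows]
        return out

    def inv_diag(self):
        d = np.asarray(self.a_inv.diagonal()).copy()
        if self.rows.size:
            d[self.rows] += np.diag(self.correction)
        return d

    def inv_dense(self):
        k = self.a_inv.toarray()
        if self.rows.size:
            k[np.ix_(self.rows, self.rows)] += self.correction
        return k


def pedigree_kinship(ped: PedigreeTable) -> PedigreeKinshipOp:
    return PedigreeKinshipOp(a_inverse(ped))


def single_step_kinship(
    ped: PedigreeTable,
    genotyped_ids,
    genotypes: np.ndarray,
    base_freqs: np.ndarray | None = None,
    ridge: float = G_RIDGE,
    blend: float = 0.05,
):
    """Build the single-step kinship operator for the full pedigree.

    ``genotypes`` rows must match ``genotyped_ids``.  Centering frequencies
    are observed in the genotyped set unless ``base_freqs`` is given.
    ``blend`` mixes A22 into G before inversion (G can be rank-deficient
    whenever fewer markers than animals are genotyped).
    """
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    f = inbreeding_meuwissen_luo(ped)
    a_inv = a_inverse(ped, f)
    if genotyped_ids.size == 0:
        return PedigreeKinshipOp(a_inv)
    g = build_G(genotypes, freqs=base_freqs, ids=genotyped_ids)
    a22 = a_submatrix(ped, genotyped_ids)
    gv = (1.0 - blend) * g.values + blend * a22.values + ridge * np.eye(g.values.shape[0])
    correction = np.linalg.inv(gv) - np.linalg.inv(a22.values)
    diagnostics = {
        "cor_diag": diag_cor_G_A22(g.values, a22.values, "diag"),
        "cor_offdiag": diag_cor_G_A22(g.values, a22.values, "offdiag") if genotyped_ids.size > 1 else float("nan"),
    }
    return SingleStepKinshipOp(a_inv, ped.rows(genotyped_ids), correction, diagnostics)


@dataclass
class MMEProblem:
    """Phenotypes (nan = missing), variance components, and a kinship operator.

    Row ``i`` of ``phenotypes`` belongs to the animal at position ``i`` of
    the kinship operator's index (pedigree order for A / H operators).
    """

    phenotypes: np.ndarray  # (n, T) with nan for missing
    genetic_cov: np.ndarray  # (T, T)
    residual_var: np.ndarray  # (T,)
    kinship: object

    def __post_init__(self):
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        self.residual_var = np.asarray(self.residual_var, dtype=float)
        if self.phenotypes.shape[0] != self.kinship.n:
            raise ValueError("phenotype rows must match kinship dimension")


@dataclass
class EBVTable:
    """Estimated breeding values per animal per trait plus the index."""

    ebv: np.ndarray  # (n, T)
    means: np.ndarray  # (T,) fixed effects
    index_weights: np.ndarray = None

    def __post_init__(self):
        if self.index_weights is None:
            self.index_weights = INDEX_WEIGHTS.copy()

    @property
    def index(self) -> np.ndarray:
        return self.ebv @ self.index_weights

    def to_frame(self, animal_ids=None, eval_time: float | None = None, genotyped=None):
        import pandas as pd

        n = self.ebv.shape[0]
        out = pd.DataFrame(
            {
                "animal_id": np.arange(1, n + 1) if animal_ids is None else np.asarray(animal_ids),
                "eval_time": eval_time,
                "ebv_t1": self.ebv[:, 0],
                "ebv_t2": self.ebv[:, 1],
                "ebv_t3": self.ebv[:, 2],
                "index": self.index,
            }
        )
        out["genotyped"] = False if genotyped is None else genotyped
        return out


def selection_index(ebv: np.ndarray | EBVTable, weights=None) -> np.ndarray:
    """Weighted sum of per-trait EBVs (weights default 0.20 / 0.35 / 0.45)."""
    if weights is None:
        weights = INDEX_WEIGHTS
    if isinstance(ebv, EBVTable):
        ebv = ebv.ebv
    return np.asarray(ebv, float) @ np.asarray(weights, float)


def solve_mme(
    problem: MMEProblem,
    tol: float = 1e-8,
    maxiter: int = 5000,
    method: str = "auto",
    x0: np.ndarray | None = None,
) -> EBVTable:
    """Solve the multi-trait mixed-model equations.

    ``method``: "dense" assembles the full coefficient matrix, "pcg" uses
    preconditioned conjugate gradients; "auto" picks dense below a size
    threshold.  Raises :class:`ConvergenceError` when the iteration cap is
    hit.
    """
    y = problem.phenotypes
    n, t = y.shape
    mask = ~np.isnan(y)
    if not mask.any():
        raise ValueError("no phenotype records at all")
    # traits without any record keep their mean pinned at zero; their EBVs
    # come through the genetic covariance with recorded traits
    inactive = ~mask.any(axis=0)
    yz = np.where(mask, y, 0.0)
    rinv = 1.0 / problem.residual_var
    g0inv = np.linalg.inv(problem.genetic_cov)
    nobs = mask.sum(axis=0)

    if method == "auto":
        method = "dense" if (t * (n + 1) <= 2400 and hasattr(problem.kinship, "inv_dense")) else "pcg"

    rhs = np.concatenate([(yz.sum(axis=0)) * rinv, (yz * rinv).T.ravel()])

    if method == "dense":
        kinv = problem.kinship.inv_dense()
        dim = t + t * n
        c = np.zeros((dim, dim))
        for a in range(t):
            c[a, a] = 1.0 if inactive[a] else nobs[a] * rinv[a]
            block = slice(t + a * n, t + (a + 1) * n)
            c[a, block] = mask[:, a] * rinv[a]
            c[block, a] = mask[:, a] * rinv[a]
            c[block, block] += np.diag(mask[:, a] * rinv[a])
            for b in range(t):
                blk2 = slice(t + b * n, t + (b + 1) * n)
                c[block, blk2] += g0inv[a, b] * kinv
        sol = np.linalg.solve(c, rhs)
    else:
        kin = problem.kinship
        mr = mask * rinv  # (n, t)

        def matvec(x):
            x = np.asarray(x, dtype=np.float64)
            b = x[:t]
            a = x[t:].reshape(t, n).T  # (n, t)
            out_b = np.where(inactive, b, nobs * rinv * b + (mr * a).sum(axis=0))
            s = kin.inv_apply(a)  # K^-1 applied column-wise
            out_a = mr * (b[None, :] + a) + s @ g0inv
            return np.concatenate([out_b, out_a.T.ravel()])

        # block-Jacobi preconditioner: one t x t block per animal (the
        # genetic correlations couple traits strongly; scalar Jacobi stalls)
        kdiag = kin.inv_diag()
        blocks = kdiag[:, None, None] * g0inv[None, :, :]
        bi = np.arange(t)
        blocks[:, bi, bi] += mr
        binv = np.linalg.inv(blocks)  # (n, t, t)
        pb = np.where(inactive, 1.0, nobs * rinv)

        def psolve(x):
            x = np.asarray(x, dtype=np.float64)
            r_a = x[t:].reshape(t, n).T
            z = np.einsum("nij,nj->ni", binv, r_a)
            return np.concatenate([x[:t] / pb, z.T.ravel()])

        dim = t + t * n
        op = spla.LinearOperator((dim, dim), matvec=matvec, dtype=np.float64)
        precond = spla.LinearOperator((dim, dim), matvec=psolve, dtype=np.float64)
        sol, info = spla.cg(op, rhs, x0=x0, rtol=tol, atol=0.0, maxiter=maxiter, M=precond)
        if info > 0:
            resid = float(np.linalg.norm(matvec(sol) - rhs) / max(np.linalg.norm(rhs), 1e-300))
            raise ConvergenceError(resid, info)

    means = sol[:t]
    ebv = sol[t:].reshape(t, n).T
    return EBVTable(ebv=ebv, means=means)


def accuracy(ebv_index: np.ndarray, tbv_index: np.ndarray, rows=None) -> float:
    """Pearson correlation between index EBVs and index true values.

    Returns nan when either side has zero variance (undefined accuracy).
    """
    e = np.asarray(ebv_index, float)
    v = np.asarray(tbv_index, float)
    if rows is not None:
        rows = np.asarray(rows, dtype=np.intp)
        e, v = e[rows], v[rows]
    if e.size < 2 or np.std(e) == 0 or np.std(v) == 0:
        return float("nan")
    return float(np.corrcoef(e, v)[0, 1])
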