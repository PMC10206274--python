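"""Pedigree (A), genomic (G), and combined (H) relationship matrices.

Three routes to numerator relationships are provided and cross-checked in
the test suite: the dense tabular method, the Meuwissen & Luo inbreeding
algorithm, and Colleau's indirect method (used to extract sub-blocks such
as A22 from large pedigrees without forming A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .inheritance import PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "build_A",
    "inbreeding_meuwissen_luo",
    "a_submatrix",
    "a_inverse",
    "build_G",
    "build_H",
    "diag_cor_G_A22",
]

#: ridge added to the diagonal of G before inversion inside the MME
G_RIDGE = 1e-6


@dataclass
class RelationshipMatrix:
    """A relationship matrix with its animal index.

    flavor is one of ``A``, ``G``, ``H``, ``A22``.  For G the centering
    frequencies and marker count are kept for provenance.
    """

    values: np.ndarray
    ids: np.ndarray
    flavor: str
    freqs: np.ndarray | None = None
    n_markers: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.values.shape != (self.ids.size, self.ids.size):
            raise ValueError("matrix/index size mismatch")

    def write_triplets(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# ids: " + " ".join(map(str, self.ids.tolist())) + "\n")
            for i in range(self.values.shape[0]):
                for j in range(i + 1):
                    fh.write(f"{i + 1} {j + 1} {self.values[i, j]:.12g}\n")


# ---------------------------------------------------------------------------
# pedigree preliminaries


def _parent_rows(ped: PedigreeTable):
    """0-based parent row arrays with -1 for unknown."""
    return ped.sire_id.astype(np.int64) - 1, ped.dam_id.astype(np.int64) - 1


@njit(cache=True)
def _ml_inbreeding(sire, dam):
    """Meuwissen & Luo inbreeding coefficients (ancestor-list traversal)."""
    n = sire.size
    f = np.zeros(n)
    w = np.zeros(n)
    heap = np.empty(n + 1, np.int64)
    inheap = np.zeros(n, np.uint8)
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            continue
        hs = 0
        heap[hs] = i
        hs += 1
        inheap[i] = 1
        w[i] = 1.0
        aii = 0.0
        while hs > 0:
            j = heap[0]
            hs -= 1
            heap[0] = heap[hs]
            k = 0
            while True:
                c = 2 * k + 1
                if c >= hs:
                    break
                if c + 1 < hs and heap[c + 1] > heap[c]:
                    c += 1
                if heap[c] > heap[k]:
                    heap[k], heap[c] = heap[c], heap[k]
                    k = c
                else:
                    break
            inheap[j] = 0
            wj = w[j]
            w[j] = 0.0
            sj, dj = sire[j], dam[j]
            if sj >= 0 and dj >= 0:
                dvar = 0.5 - 0.25 * (f[sj] + f[dj])
            elif sj >= 0:
                dvar = 0.75 - 0.25 * f[sj]
            elif dj >= 0:
                dvar = 0.75 - 0.25 * f[dj]
            else:
                dvar = 1.0
            aii += wj * wj * dvar
            if sj >= 0:
                w[sj] += 0.5 * wj
                if inheap[sj] == 0:
                    heap[hs] = sj
                    k = hs
                    hs += 1
                    while k > 0 and heap[(k - 1) // 2] < heap[k]:
                        p = (k - 1) // 2
                        heap[p], heap[k] = heap[k], heap[p]
                        k = p
                    inheap[sj] = 1
            if dj >= 0:
                w[dj] += 0.5 * wj
                if inheap[dj] == 0:
                    heap[hs] = dj
                    k = hs
                    hs += 1
                    while k > 0 and heap[(k - 1) // 2] < heap[k]:
                        p = (k - 1) // 2
                        heap[p], heap[k] = heap[k], heap[p]
                        k = p
                    inheap[dj] = 1
        f[i] = aii - 1.0
    return f


def inbreeding_meuwissen_luo(ped: PedigreeTable) -> np.ndarray:
    """Per-animal pedigree inbreeding coefficient F."""
    sire, dam = _parent_rows(ped)
    return _ml_inbreeding(sire, dam)


def _mendelian_variance(sire, dam, f):
    """Within-family (Mendelian sampling) variance per animal."""
    d = np.ones(sire.size)
    both = (sire >= 0) & (dam >= 0)
    d[both] = 0.5 - 0.25 * (f[sire[both]] + f[dam[both]])
    only_s = (sire >= 0) & (dam < 0)
    d[only_s] = 0.75 - 0.25 * f[sire[only_s]]
    only_d = (sire < 0) & (dam >= 0)
    d[only_d] = 0.75 - 0.25 * f[dam[only_d]]
    return d


@njit(cache=True)
def _tabular(sire, dam):
    n = sire.size
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[j, s]
            if d >= 0:
                v += 0.5 * a[j, d]
            a[i, j] = v
            a[j, i] = v
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * a[s, d]
        a[i, i] = aii
    return a


def _ancestor_closure(sire, dam, rows):
    """Sorted array of ``rows`` plus all their ancestors."""
    seen = np.zeros(sire.size, dtype=bool)
    stack = list(np.asarray(rows, dtype=np.int64))
    while stack:
        r = stack.pop()
        if r < 0 or seen[r]:
            continue
        seen[r] = True
        stack.append(sire[r])
        stack.append(dam[r])
    return np.flatnonzero(seen)


@njit(cache=True)
def _colleau_columns(sire, dam, dvar, cols, rows):
    """A[rows, cols] by Colleau's indirect method: A = (I-P)^-1 D (I-P)^-T."""
    n = sire.size
    out = np.empty((rows.size, cols.size))
    y = np.zeros(n)
    for c in range(cols.size):
        for t in range(n):
            y[t] = 0.0
        y[cols[c]] = 1.0
        for i in range(n - 1, -1, -1):
            yi = y[i]
            if yi != 0.0:
                if sire[i] >= 0:
                    y[sire[i]] += 0.5 * yi
                if dam[i] >= 0:
                    y[dam[i]] += 0.5 * yi
        for t in range(n):
            y[t] *= dvar[t]
        for i in range(n):
            v = y[i]
            if sire[i] >= 0:
                v += 0.5 * y[sire[i]]
            if dam[i] >= 0:
                v += 0.5 * y[dam[i]]
            y[i] = v
        for r in range(rows.size):
            out[r, c] = y[rows[r]]
    return out


def a_submatrix(ped: PedigreeTable, ids) -> RelationshipMatrix:
    """Numerator relationships among ``ids`` without forming the full A."""
    sire, dam = _parent_rows(ped)
    rows = ped.rows(ids)
    f = _ml_inbreeding(sire, dam)
    dvar = _mendelian_variance(sire, dam, f)
    vals = _colleau_columns(sire, dam, dvar, rows.astype(np.int64), rows.astype(np.int64))
    vals = 0.5 * (vals + vals.T)
    return RelationshipMatrix(values=vals, ids=np.asarray(ids, np.int64), flavor="A")


#: closure size above which build_A switches from the tabular method
TABULAR_LIMIT = 6000


def build_A(ped: PedigreeTable, subset=None) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix for ``subset`` (default: all).

    Ancestors are always included in the recursion (pedigree never
    truncated).  Small closures use the dense tabular method; large ones
    fall back to Colleau's indirect method.
    """
    sire, dam = _parent_rows(ped)
    if subset is None:
        subset = ped.animal_id
    rows = ped.rows(subset)
    closure = _ancestor_closure(sire, dam, rows)
    if closure.size > TABULAR_LIMIT:
        return a_submatrix(ped, subset)
    local = -np.ones(ped.n, dtype=np.int64)
    local[closure] = np.arange(closure.size)
    ls = np.where(sire[closure] >= 0, local[sire[closure]], -1)
    ld = np.where(dam[closure] >= 0, local[dam[closure]], -1)
    a_full = _tabular(ls, ld)
    sel = local[rows]
    return RelationshipMatrix(values=a_full[np.ix_(sel, sel)], ids=np.asarray(subset, np.int64), flavor="A")


def a_inverse(ped: PedigreeTable, f: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of the full numerator relationship matrix (Henderson
    rules with inbreeding)."""
    sire, dam = _parent_rows(ped)
    if f is None:
        f = _ml_inbreeding(sire, dam)
    dvar = _mendelian_variance(sire, dam, f)
    b = 1.0 / dvar
    n = ped.n
    i_idx, j_idx, v = [], [], []
    rows = np.arange(n)

    def _add(ii, jj, vv):
        i_idx.append(ii)
        j_idx.append(jj)
        v.append(vv)

    _add(rows, rows, b)
    for par in (sire, dam):
        m = par >= 0
        _add(rows[m], par[m], -0.5 * b[m])
        _add(par[m], rows[m], -0.5 * b[m])
        _add(par[m], par[m], 0.25 * b[m])
    both = (sire >= 0) & (dam >= 0)
    _add(sire[both], dam[both], 0.25 * b[both])
    _add(dam[both], sire[both], 0.25 * b[both])
    mat = sp.coo_matrix(
        (np.concatenate(v), (np.concatenate(i_idx), np.concatenate(j_idx))), shape=(n, n)
    )
    return mat.tocsr()


# ---------------------------------------------------------------------------
# genomic relationships


def build_G(genotypes: np.ndarray, freqs: np.ndarray | None = None, ids=None) -> RelationshipMatrix:
    """G = W W' / (2 sum p_j (1 - p_j)) with W centred by 2 p_j.

    ``genotypes`` is an (animals x markers) 0/1/2 dosage matrix; ``freqs``
    default to the frequencies observed in this genotyped set.
    """
    geno = np.asarray(genotypes, dtype=float)
    if freqs is None:
        freqs = geno.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all markers monomorphic: G undefined")
    w = geno - 2.0 * freqs
    g = (w @ w.T) / denom
    if ids is None:
        ids = np.arange(1, geno.shape[0] + 1)
    return RelationshipMatrix(values=g, ids=np.asarray(ids, np.int64), flavor="G", freqs=freqs, n_markers=freqs.size)


def build_H(a: RelationshipMatrix, g: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """H = A + [[0, 0], [0, G - A22]] on A's animal index."""
    genotyped_ids = np.asarray(genotyped_ids, np.int64)
    pos = {int(i): k for k, i in enumerate(a.ids)}
    try:
        sel = np.array([pos[int(i)] for i in genotyped_ids], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"genotyped id {exc} not in A's index") from exc
    gpos = {int(i): k for k, i in enumerate(g.ids)}
    gsel = np.array([gpos[int(i)] for i in genotyped_ids], dtype=np.intp)
    h = a.values.copy()
    if sel.size:
        a22 = a.values[np.ix_(sel, sel)]
        h[np.ix_(sel, sel)] += g.values[np.ix_(gsel, gsel)] - a22
    return RelationshipMatrix(values=h, ids=a.ids, flavor="H")


def diag_cor_G_A22(g: np.ndarray | RelationshipMatrix, a22: np.ndarray | RelationshipMatrix, part: str = "diag") -> float:
    """Diagnostic correlation between G and A22 (never halts a run).

    ``part`` selects diagonals, off-diagonals, or all entries, since the
    convention is ambiguous in evaluation software.
    """
    gv = g.values if isinstance(g, RelationshipMatrix) else np.asarray(g, float)
    av = a22.values if isinstance(a22, RelationshipMatrix) else np.asarray(a22, float)
    if gv.shape != av.shape:
        raise ValueError("G and A22 must share an index")
    n = gv.shape[0]
    if part == "diag":
        x, y = np.diag(gv), np.diag(av)
    elif part == "offdiag":
        m = ~np.eye(n, dtype=bool)
        x, y = gv[m], av[m]
    elif part == "all":
        x, y = gv.ravel(), av.ravel()
    else:
        raise ValueError("part must be diag, offdiag, or all")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
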