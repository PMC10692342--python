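"""Relationship matrices: pedigree A, genomic G/Gw, and single-step H.

The numerator relationship matrix A is built by the tabular method with
inbreeding; its sparse inverse comes from Henderson's rules with the
Mendelian-sampling variances implied by parental inbreeding.  The genomic
matrix follows VanRaden's first method, G = ZZ'/(2Σp(1−p)) with Z the
genotype matrix centred at twice the observed allele frequencies.  G is
blended with the pedigree relationships among genotyped animals,
Gw = w·G + (1−w)·A22, and the single-step matrix combines pedigree and
genomic information either through its inverse,

    H⁻¹ = A⁻¹ + [0 0; 0 Gw⁻¹ − A22⁻¹]  (genotyped block),

or directly as H = A + A(:,g) A22⁻¹ (Gw − A22) A22⁻¹ A(g,:).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "sort_pedigree",
    "build_A",
    "a_inverse",
    "allele_freq",
    "snp_qc",
    "build_G",
    "prune_high_relationship",
    "blend_and_H_inverse",
    "build_H",
]


def _parent_arrays(pedigree: pd.DataFrame):
    ids = pedigree["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    pos = {v: i for i, v in enumerate(ids)}
    unknown = {0, "0", None}

    def code(col):
        out = np.full(len(ids), -1, dtype=np.int64)
        for i, v in enumerate(pedigree[col].tolist()):
            if v in unknown or (isinstance(v, float) and np.isnan(v)):
                continue
            if v not in pos:
                raise ValueError(f"parent {v!r} of {ids[i]!r} not in pedigree")
            out[i] = pos[v]
        return out

    return ids, code("sire"), code("dam")


def sort_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort (parents before offspring); raises on cycles.

    Columns: id, sire, dam with 0/NaN/None marking unknown parents.
    """
    ids, sire, dam = _parent_arrays(pedigree)
    n = len(ids)
    order, state = [], np.zeros(n, dtype=np.int8)  # 0 new, 1 open, 2 done

    for root in range(n):
        if state[root]:
            continue
        stack = [root]
        while stack:
            i = stack[-1]
            if state[i] == 2:
                stack.pop()
                continue
            state[i] = 1
            pending = []
            for p in (sire[i], dam[i]):
                if p >= 0 and state[p] != 2:
                    if state[p] == 1:
                        cyc = [ids[j] for j in stack[stack.index(p):]]
                        raise ValueError(f"pedigree cycle detected: {cyc}")
                    pending.append(p)
            if pending:
                stack.extend(pending)
            else:
                state[i] = 2
                order.append(i)
                stack.pop()
    return pedigree.iloc[order].reset_index(drop=True)


def build_A(pedigree: pd.DataFrame):
    """Numerator relationship matrix by the tabular method.

    Returns (A, ids) with A dense in topological order,
    diag(A) = 1 + inbreeding coefficient.
    """
    ped = sort_pedigree(pedigree)
    ids, sire, dam = _parent_arrays(ped)
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A, ids


def a_inverse(pedigree: pd.DataFrame):
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    Returns (A_inv csr, ids) in the same (topological) order as build_A.
    """
    A, ids = build_A(pedigree)
    ped = sort_pedigree(pedigree)
    _, sire, dam = _parent_arrays(ped)
    F = np.diag(A) - 1.0
    n = len(ids)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i), cols.append(j), vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            m = 0.75 - 0.25 * F[max(s, d)]
        else:
            m = 1.0
        a = 1.0 / m
        add(i, i, a)
        for p in (s, d):
            if p >= 0:
                add(i, p, -a / 2), add(p, i, -a / 2)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, a / 4)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n)), ids


def allele_freq(geno: np.ndarray) -> np.ndarray:
    """Observed allele frequency per SNP; missing entries (NaN) ignored."""
    return np.nanmean(np.asarray(geno, dtype=float), axis=0) / 2.0


def snp_qc(geno, chromosomes, hwe_alpha: float = 1e-6, autosomes=None):
    """SNP quality control: call rate > 0.95, MAF > 0.05, autosomal, HWE.

    ``geno`` is individuals × SNPs in {0, 1, 2, NaN}.  ``chromosomes`` labels
    each SNP; ``autosomes`` is the set of labels treated as autosomal
    (default: integer labels 1–29, the bovine autosomes).  The HWE test is a
    one-degree chi-square on the genotype counts, removal at p < hwe_alpha.

    Returns (kept column mask, report dict).
    """
    g = np.asarray(geno, dtype=float)
    chrom = np.asarray(chromosomes)
    if autosomes is None:
        autosomes = {str(c) for c in range(1, 30)}
    obs = ~np.isnan(g)
    call = obs.mean(axis=0)
    p = allele_freq(g)
    maf = np.minimum(p, 1.0 - p)

    n0 = np.sum((g == 0) & obs, axis=0).astype(float)
    n1 = np.sum(g == 1, axis=0).astype(float)
    n2 = np.sum(g == 2, axis=0).astype(float)
    ntot = n0 + n1 + n2
    q = np.where(ntot > 0, (2 * n2 + n1) / np.maximum(2 * ntot, 1), 0.0)
    e0, e1, e2 = ntot * (1 - q) ** 2, 2 * ntot * q * (1 - q), ntot * q**2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            (e0 > 0) & (e1 > 0) & (e2 > 0),
            (n0 - e0) ** 2 / np.maximum(e0, 1e-300)
            + (n1 - e1) ** 2 / np.maximum(e1, 1e-300)
            + (n2 - e2) ** 2 / np.maximum(e2, 1e-300),
            np.inf,
        )
    hwe_p = stats.chi2.sf(chi2, df=1)

    auto = np.array([str(c) in autosomes for c in chrom])
    fail_call = call <= 0.95
    fail_maf = maf <= 0.05
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_call | fail_maf | ~auto | fail_hwe)
    report = {
        "n_input": g.shape[1],
        "fail_call_rate": int(fail_call.sum()),
        "fail_maf": int(fail_maf.sum()),
        "fail_autosome": int((~auto).sum()),
        "fail_hwe": int(fail_hwe.sum()),
        "n_kept": int(keep.sum()),
        "hwe_alpha": hwe_alpha,
    }
    if report["n_kept"] == 0:
        raise ValueError(f"all SNPs removed by QC: {report}")
    return keep, report


def build_G(geno: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Missing genotypes are mean-imputed (2p per SNP); frequencies are taken
    from the genotyped animals themselves.
    """
    g = np.array(geno, dtype=float)
    p = allele_freq(g)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    fill = np.broadcast_to(2.0 * p, g.shape)
    g = np.where(np.isnan(g), fill, g)
    Z = g - 2.0 * p
    return (Z @ Z.T) / denom


def prune_high_relationship(G: np.ndarray, ids, threshold: float = 0.95):
    """Greedily drop individuals until no off-diagonal relationship exceeds
    ``threshold``.

    At each step the individual involved in the most violations goes; ties
    are broken by dropping the lexicographically larger id.  Returns the
    retained ids in the original order.
    """
    ids = list(ids)
    G = np.asarray(G, dtype=float)
    active = list(range(len(ids)))
    while True:
        sub = G[np.ix_(active, active)].copy()
        np.fill_diagonal(sub, -np.inf)
        viol = sub > threshold
        counts = viol.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        cand = [active[k] for k in range(len(active)) if counts[k] == worst]
        drop = max(cand, key=lambda i: str(ids[i]))
        active.remove(drop)
    return [ids[i] for i in active]


def blend_and_H_inverse(G, A, genotyped_idx, blend_w: float = 0.95):
    """Blend G with A22 and assemble the single-step inverse.

    Gw = blend_w·G + (1−blend_w)·A22;
    H⁻¹ = A⁻¹ + (Gw⁻¹ − A22⁻¹) padded onto the genotyped block.

    Returns (Gw, H_inv dense).  With no genotyped animals or blend_w = 0,
    H⁻¹ equals A⁻¹ exactly.
    """
    A = np.asarray(A, dtype=float)
    g = np.asarray(genotyped_idx, dtype=int)
    A_inv = np.linalg.inv(A)
    if len(g) == 0:
        return np.zeros((0, 0)), A_inv
    A22 = A[np.ix_(g, g)]
    Gw = blend_w * np.asarray(G, dtype=float) + (1.0 - blend_w) * A22
    try:
        Gw_inv = np.linalg.inv(Gw)
        if not np.all(np.isfinite(Gw_inv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "Gw is singular; lower blend_w to add more pedigree information"
        ) from err
    H_inv = A_inv.copy()
    H_inv[np.ix_(g, g)] += Gw_inv - np.linalg.inv(A22)
    return Gw, H_inv


def build_H(A, Gw, genotyped_idx) -> np.ndarray:
    """Single-step relationship matrix from the joint-distribution identity.

    H = A + A(:,g) A22⁻¹ (Gw − A22) A22⁻¹ A(g,:); equals inv(H⁻¹) from
    :func:`blend_and_H_inverse` and is cheap when few animals are genotyped.
    """
    A = np.asarray(A, dtype=float)
    g = np.asarray(genotyped_idx, dtype=int)
    if len(g) == 0:
        return A.copy()
    A22 = A[np.ix_(g, g)]
    B = np.linalg.solve(A22, A[g, :])  # A22⁻¹ A(g,:)
    return A + B.T @ (np.asarray(Gw) - A22) @ B
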