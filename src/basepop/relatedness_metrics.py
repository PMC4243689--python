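"""Molecular (IBS) coancestry, expected heterozygosity and pedigree kinship.

Molecular coancestry between individuals i and j is the probability that
two alleles, one drawn at random from each individual at a random marker
locus, are identical in state (Malecot-style kinship without allele
frequency correction).  Averaged over a group including self-pairs it
satisfies the exact identity

    group coancestry = 1 - He

on the same loci, which is what makes minimising group coancestry
equivalent to maximising expected heterozygosity.

Pedigree coancestry and inbreeding use the standard tabular method with
founders assumed unrelated and non-inbred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "molecular_coancestry",
    "strain_mean_coancestry",
    "group_coancestry",
    "expected_heterozygosity",
    "pedigree_coancestry",
    "rate",
]


def molecular_coancestry(dosages: np.ndarray) -> np.ndarray:
    """IBS coancestry matrix from biallelic dosages.

    For a locus where i carries allele-1 dosage ``d_i``, the probability
    that one allele drawn from i and one from j match in state is
    ``q_i q_j + (1-q_i)(1-q_j)`` with ``q = d/2`` — identical to averaging
    the indicator over the four ordered allele pairs.  The matrix is the
    mean of this over loci; self-coancestry is computed the same way
    (1 for a homozygote, 0.5 for a heterozygote).

    Parameters
    ----------
    dosages
        Array of shape ``(n_individuals, n_loci)`` with values in {0, 1, 2}.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    if dosages.ndim != 2 or dosages.shape[1] < 1:
        raise ValueError("need a (n, L) dosage matrix with at least one locus")
    q = dosages / 2.0
    l = q.shape[1]
    return (q @ q.T + (1.0 - q) @ (1.0 - q).T) / l


def strain_mean_coancestry(
    coancestry: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average an individual coancestry matrix into strain blocks.

    Entry (s, t) is the mean of f_ij over all ordered pairs with i in s and
    j in t; the diagonal therefore includes self-pairs i = j, which is what
    keeps the heterozygosity identity exact at the strain level.

    Returns ``(strain_ids, matrix)`` with strains in sorted label order.
    """
    labels = np.asarray(labels)
    if len(labels) != coancestry.shape[0]:
        raise ValueError("labels and matrix size mismatch")
    strain_ids = np.unique(labels)
    idx = [np.flatnonzero(labels == s) for s in strain_ids]
    if any(len(i) == 0 for i in idx):
        raise ValueError("empty strain")
    k = len(strain_ids)
    out = np.empty((k, k))
    for a in range(k):
        for b in range(a, k):
            block = coancestry[np.ix_(idx[a], idx[b])]
            out[a, b] = out[b, a] = block.mean()
    return strain_ids, out


def group_coancestry(coancestry: np.ndarray) -> float:
    """Mean coancestry over all ordered pairs, self-pairs included."""
    return float(np.asarray(coancestry).mean())


def expected_heterozygosity(dosages: np.ndarray) -> float:
    """Mean over loci of ``2 p (1 - p)`` where p is the allele-1 frequency
    in the group."""
    dosages = np.asarray(dosages, dtype=np.float64)
    if dosages.ndim != 2 or dosages.size == 0:
        raise ValueError("need a non-empty (n, L) dosage matrix")
    p = dosages.mean(axis=0) / 2.0
    return float(np.mean(2.0 * p * (1.0 - p)))


def pedigree_coancestry(
    pedigree: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genealogical coancestry and inbreeding by the tabular method.

    Parameters
    ----------
    pedigree
        DataFrame with columns ``id``, ``sire``, ``dam`` (parent ids, -1 or
        missing for founders), ordered so parents precede offspring.

    Returns
    -------
    ids : ndarray
        Individual ids in pedigree order.
    kinship : ndarray
        Matrix with f_ij off-diagonal and self-coancestry (1 + F_i)/2 on
        the diagonal; founders have f_ii = 0.5, f_ij = 0, F = 0.
    inbreeding : ndarray
        F_i = f(sire_i, dam_i), 0 for founders.
    """
    ids = pedigree["id"].to_numpy()
    sires = pedigree["sire"].fillna(-1).astype(np.int64).to_numpy()
    dams = pedigree["dam"].fillna(-1).astype(np.int64).to_numpy()
    n = len(ids)
    if len(np.unique(ids)) != n:
        raise ValueError("duplicate ids in pedigree")
    row = {int(i): k for k, i in enumerate(ids)}
    kin = np.zeros((n, n))
    inb = np.zeros(n)
    for k in range(n):
        s, d = int(sires[k]), int(dams[k])
        si = row.get(s, -1) if s >= 0 else -1
        di = row.get(d, -1) if d >= 0 else -1
        if (s >= 0 and si < 0) or (d >= 0 and di < 0):
            raise ValueError("parent id missing from pedigree")
        if si >= k or di >= k:
            raise ValueError("pedigree not ordered: parent after offspring")
        if si >= 0 and di >= 0:
            inb[k] = kin[si, di]
            vals = 0.5 * (kin[:k, si] + kin[:k, di])
        elif si >= 0:
            vals = 0.5 * kin[:k, si]
        elif di >= 0:
            vals = 0.5 * kin[:k, di]
        else:
            vals = np.zeros(k)
        kin[k, :k] = vals
        kin[:k, k] = vals
        kin[k, k] = 0.5 * (1.0 + inb[k])
    return ids, kin, inb


def rate(series: np.ndarray) -> np.ndarray:
    """Per-generation rate of change of inbreeding or coancestry:
    ``delta_t = (x_t - x_{t-1}) / (1 - x_{t-1})``."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if np.any(x[:-1] >= 1.0):
        raise ValueError("rate undefined when a value reaches 1")
    return (x[1:] - x[:-1]) / (1.0 - x[:-1])
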