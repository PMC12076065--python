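"""Pedigree and genomic relationship matrices; genomic family correction.

The additive (numerator) relationship matrix A is built by the tabular
recursion over a topologically ordered pedigree; the genomic matrix G follows
VanRaden's first method from SNP dosages.  Open-pollinated family labels are
verified and corrected by comparing each tree's mean genomic relationship to
every half-sib family (expected 0.25 within the true family, ~0 elsewhere).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["a_matrix", "vanraden_g", "FamilyAssigner", "assign_families", "sort_pedigree"]

log = logging.getLogger(__name__)

UNASSIGNED_FLOOR = 0.125  # half the half-sib expectation


def sort_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Topologically order a pedigree (parents before offspring).

    Raises on cycles, reporting the offending chain.
    """
    import networkx as nx

    ped = pedigree.reset_index(drop=True)
    g = nx.DiGraph()
    g.add_nodes_from(ped["id"])
    known = set(ped["id"])
    for row in ped.itertuples():
        for parent in (row.dam, row.sire):
            if isinstance(parent, str) and parent in known:
                g.add_edge(parent, row.id)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        chain = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise ValueError(f"pedigree contains a cycle: {chain}")
    pos = {i: k for k, i in enumerate(order)}
    return ped.iloc[np.argsort([pos[i] for i in ped["id"]])].reset_index(drop=True)


def a_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + F_i (F_i = half the parents' relationship) and
    A_ij = mean of A over j's known parents; unknown parents are assumed
    unrelated founders, so two offspring of one dam with unknown unrelated
    sires get the half-sib value 0.25.
    """
    ped = sort_pedigree(pedigree)
    ids = ped["id"].tolist()
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    dams = [idx.get(d) if isinstance(d, str) else None for d in ped["dam"]]
    sires = [idx.get(s) if isinstance(s, str) else None for s in ped["sire"]]
    for i in range(n):
        di, si = dams[i], sires[i]
        A[i, i] = 1.0 + (0.5 * A[di, si] if di is not None and si is not None else 0.0)
        for j in range(i):
            val = 0.0
            if di is not None:
                val += 0.5 * A[j, di]
            if si is not None:
                val += 0.5 * A[j, si]
            A[i, j] = A[j, i] = val
    return pd.DataFrame(A, index=ids, columns=ids)


def vanraden_g(genotypes: pd.DataFrame, maf_floor=0.01, max_missing=0.5,
               allele_freq=None) -> pd.DataFrame:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    G = ZZ' / (2 sum p_k (1 - p_k)) with Z the dosage matrix centred at twice
    the allele frequencies (estimated from the sample unless base-population
    frequencies are supplied via ``allele_freq``); missing dosages are
    mean-imputed (zero after centring).  Markers below ``maf_floor`` or above
    ``max_missing`` missingness are dropped; at least two polymorphic markers
    must remain.
    """
    M = genotypes.to_numpy(dtype=float)
    ids = genotypes.index
    miss = np.isnan(M)
    if allele_freq is not None:
        p = np.asarray(allele_freq, dtype=float)
    else:
        p = np.nanmean(M, axis=0) / 2.0
    keep = (
        (np.minimum(p, 1 - p) >= maf_floor)
        & (miss.mean(axis=0) <= max_missing)
        & np.isfinite(p)
    )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable polymorphic markers after filtering")
    M = M[:, keep]
    p = p[keep]
    Z = np.where(np.isnan(M), 0.0, M - 2 * p)
    denom = 2.0 * np.sum(p * (1 - p))
    G = (Z @ Z.T) / denom
    return pd.DataFrame(G, index=ids, columns=ids)


class FamilyAssigner(BaseEstimator):
    """Correct half-sib family assignments from genomic relationships.

    For every individual the mean genomic relationship to each candidate
    family (self excluded) is computed; the individual is assigned to the
    family with the maximum mean relationship.  If that maximum is below
    ``unassigned_floor`` (default half the 0.25 half-sib expectation) the
    individual is left unassigned.  Ties keep the original label
    (conservative correction).

    Fitted attributes
    -----------------
    assignments_ : DataFrame with id, old_family, new_family, best_mean,
        changed.
    report_ : the subset of assignments_ with changed labels.
    pedigree_ : the corrected pedigree.
    """

    def __init__(self, unassigned_floor=UNASSIGNED_FLOOR):
        self.unassigned_floor = unassigned_floor

    def fit(self, G: pd.DataFrame, pedigree: pd.DataFrame):
        ped = pedigree.reset_index(drop=True)
        offspring = ped[ped["dam"].notna() | ped["sire"].notna()]
        members = {}
        for fam, g in offspring.groupby("family"):
            ids = [i for i in g["id"] if i in G.index]
            members[fam] = ids
            if len(ids) == 1:
                log.warning("family %s has a single genotyped member", fam)
        fams = sorted(members)
        Gm = G.to_numpy()
        pos = {i: k for k, i in enumerate(G.index)}
        ind = np.zeros((len(G.index), len(fams)))
        for c, fam in enumerate(fams):
            for j in members[fam]:
                ind[pos[j], c] = 1.0
        sums = Gm @ ind  # (n, F) sum of relationships to each family
        counts = ind.sum(axis=0)

        rows = []
        for rec in offspring.itertuples():
            if rec.id not in pos:
                continue
            i = pos[rec.id]
            old = rec.family
            s = sums[i].copy()
            c = counts.copy()
            # exclude self from its own (current) family mean
            self_fams = ind[i] > 0
            s[self_fams] -= Gm[i, i]
            c = c - self_fams
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(c > 0, s / np.maximum(c, 1), -np.inf)
            best = int(np.argmax(means))
            best_val = float(means[best])
            best_fam = fams[best]
            if old in fams and abs(means[fams.index(old)] - best_val) <= 1e-12:
                best_fam = old  # tie: keep the original label
            if best_val < self.unassigned_floor:
                best_fam = None
            rows.append((rec.id, old, best_fam, best_val, best_fam != old))
        self.assignments_ = pd.DataFrame(
            rows, columns=["id", "old_family", "new_family", "best_mean", "changed"]
        )
        self.report_ = self.assignments_[self.assignments_["changed"]].reset_index(drop=True)
        new_map = dict(zip(self.assignments_["id"], self.assignments_["new_family"]))
        ped2 = ped.copy()
        founders = ped[ped["dam"].isna() & ped["sire"].isna()]
        dam_of = dict(zip(founders["family"], founders["id"]))
        for k, rec in ped2.iterrows():
            if rec["id"] in new_map:
                nf = new_map[rec["id"]]
                ped2.loc[k, "family"] = nf
                ped2.loc[k, "dam"] = dam_of.get(nf) if nf is not None else None
        self.pedigree_ = ped2
        return self

    def predict(self, ids=None):
        """Corrected family label per id (None = unassigned)."""
        a = self.assignments_
        mapping = dict(zip(a["id"], a["new_family"]))
        if ids is None:
            return mapping
        return [mapping.get(i) for i in ids]


def assign_families(G, current_pedigree, unassigned_floor=UNASSIGNED_FLOOR):
    """Functional wrapper over FamilyAssigner: returns (corrected pedigree,
    change report)."""
    fa = FamilyAssigner(unassigned_floor=unassigned_floor).fit(G, current_pedigree)
    return fa.pedigree_, fa.report_
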