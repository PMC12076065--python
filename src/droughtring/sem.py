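"""Piecewise structural equation modeling with mixed-model components.

A causal hypothesis over tree traits is expressed as a directed acyclic
graph; each node with parents gets its own linear mixed model (random
intercepts for the experimental design — site, block, set — and family).
Goodness of fit follows the d-separation logic: every independence claim in
the basis set (non-adjacent pairs, conditioned on the parents of the
downstream node) is tested by adding the putative independent variable to
the downstream node's component model, and the claim p-values combine into
Fisher's C = -2 sum ln p, chi-squared with 2k degrees of freedom.  A global
p above 0.05 means no important relationship is missing; rejected claims are
returned as candidate missing links.

All responses are modeled as Gaussian (the ordinal gall-rust score included,
a deliberate simplification); component p-values use a normal approximation
to the Wald t, adequate at the ~10^3 observations these models see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .lmm import _dummies
from .reml import REMLProblem

__all__ = [
    "SEMSpec",
    "PiecewiseSEM",
    "build_basis_set",
    "fit_components",
    "fishers_c",
    "missing_links",
    "default_spec",
]

log = logging.getLogger(__name__)

DEFAULT_GROUPS = ("site", "block_id", "set_id", "family")


@dataclass
class SEMSpec:
    """A directed acyclic trait model.

    edges: (source, target) pairs; correlated_errors: unordered pairs whose
    association is modeled as free (e.g. height and DBH); groups: random
    intercept factors applied to every component model.
    """

    edges: list
    correlated_errors: list = field(default_factory=list)
    groups: tuple = DEFAULT_GROUPS
    extra_nodes: list = field(default_factory=list)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        g.add_nodes_from(self.extra_nodes)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            chain = " -> ".join(e[0] for e in cyc) + " -> " + cyc[-1][1]
            raise ValueError(f"SEM graph has a cycle: {chain}")
        return g

    @property
    def nodes(self):
        return list(nx.topological_sort(self.graph()))

    @classmethod
    def from_dict(cls, d):
        return cls(
            edges=[tuple(e) for e in d.get("edges", [])],
            correlated_errors=[tuple(e) for e in d.get("correlated_errors", [])],
            groups=tuple(d.get("groups", DEFAULT_GROUPS)),
            extra_nodes=list(d.get("extra_nodes", [])),
        )

    def to_dict(self):
        return {
            "edges": [list(e) for e in self.edges],
            "correlated_errors": [list(e) for e in self.correlated_errors],
            "groups": list(self.groups),
            "extra_nodes": list(self.extra_nodes),
        }


def default_spec(groups=DEFAULT_GROUPS) -> SEMSpec:
    """The theoretical trait model for the drought study.

    Competition, gall-rust infection, water-use efficiency (delta13C) and
    wood density are hypothesized drivers of resilience to each drought
    event; resilience, competition and gall rust drive long-term decline;
    decline drives final height and DBH, whose errors are correlated.
    """
    drivers = ["competition", "gall_rust", "d13c", "wood_density"]
    edges = [(d, r) for d in drivers for r in ("resilience_2002", "resilience_2010")]
    edges += [
        ("resilience_2002", "decline"),
        ("resilience_2010", "decline"),
        ("competition", "decline"),
        ("gall_rust", "decline"),
        ("decline", "height35"),
        ("decline", "dbh35"),
    ]
    return SEMSpec(edges=edges, correlated_errors=[("height35", "dbh35")], groups=groups)


# ------------------------------------------------------------------ basis set


def build_basis_set(spec: SEMSpec):
    """Shipley's d-separation basis set for a directed acyclic trait model.

    One claim per non-adjacent pair, conditioned on the parents of the
    downstream node; pairs declared correlated-error and pairs of two
    exogenous nodes (whose association the model leaves free) are excluded.

    Returns a list of (x, y, conditioning tuple) with y the downstream node.
    """
    g = spec.graph()
    order = {n: k for k, n in enumerate(nx.topological_sort(g))}
    corr = {frozenset(p) for p in spec.correlated_errors}
    claims = []
    nodes = sorted(g.nodes, key=order.get)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if g.has_edge(a, b) or g.has_edge(b, a):
                continue
            if frozenset((a, b)) in corr:
                continue
            if g.in_degree(a) == 0 and g.in_degree(b) == 0:
                continue  # exogenous association left free
            x, y = (a, b) if order[a] < order[b] else (b, a)
            if nx.has_path(g, y, x):  # y must not be an ancestor of x
                x, y = y, x
            claims.append((x, y, tuple(sorted(g.predecessors(y)))))
    return claims


# ----------------------------------------------------------- component models


def _mixed_fit(data, response, predictors, groups, method="ai", tol=1e-8):
    """REML mixed model: response ~ predictors + random group intercepts.

    Returns (beta Series over ['(mu)'] + predictors, se Series, n).
    """
    cols = [response, *predictors, *groups]
    d = data[cols].dropna().reset_index(drop=True)
    y = d[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d))] + [d[p].to_numpy(dtype=float) for p in predictors])
    names = ["(mu)"] + list(predictors)
    factors = []
    for gcol in groups:
        Z, levels = _dummies(d[gcol])
        if len(levels) > 1:
            factors.append((gcol, Z))
    try:
        prob = REMLProblem(y, X, factors=factors)
    except ValueError as err:
        raise ValueError(f"component model for '{response}' is singular: {err}") from err
    res = prob.fit(method=method, tol=tol, max_iter=500)
    beta = pd.Series(res.beta, index=names)
    se = pd.Series(np.sqrt(np.diag(res.cov_beta)), index=names)
    return beta, se, len(d), d


def fit_components(spec: SEMSpec, data: pd.DataFrame, method="ai"):
    """Fit every component model; returns a tidy coefficient table.

    Standardized coefficients are b * sd(x)/sd(y) over the component model's
    complete cases; p-values are two-sided normal approximations to the Wald
    statistic.
    """
    rows = []
    g = spec.graph()
    for node in spec.nodes:
        parents = sorted(g.predecessors(node))
        if not parents:
            continue
        beta, se, n, d = _mixed_fit(data, node, parents, spec.groups, method=method)
        sy = d[node].std()
        for parent in parents:
            b = beta[parent]
            z = b / se[parent] if se[parent] > 0 else np.inf
            p = 2 * stats.norm.sf(abs(z))
            sc = b * d[parent].std() / sy if sy > 0 else np.nan
            rows.append((parent, node, b, se[parent], sc, p, n))
    return pd.DataFrame(
        rows, columns=["source", "target", "estimate", "se", "std_coef", "p", "n"]
    )


def _test_claim(data, claim, groups, method="ai"):
    x, y, cond = claim
    beta, se, n, _ = _mixed_fit(data, y, list(cond) + [x], groups, method=method)
    z = beta[x] / se[x] if se[x] > 0 else np.inf
    return 2 * stats.norm.sf(abs(z))


def fishers_c(claim_pvalues):
    """Fisher's C = -2 sum ln p with 2k df and its chi-squared upper tail.

    Any p of exactly zero makes C infinite (reported as a failed fit with
    global p = 0).
    """
    ps = np.asarray(list(claim_pvalues), dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("claim p-values must lie in [0, 1]")
    k = len(ps)
    df = 2 * k
    if k == 0:
        return 0.0, 0, 1.0
    if np.any(ps == 0):
        return np.inf, df, 0.0
    C = -2.0 * np.log(ps).sum()
    return float(C), df, float(stats.chi2.sf(C, df))


def missing_links(spec: SEMSpec, data: pd.DataFrame, alpha=0.05, method="ai"):
    """Independence claims rejected at ``alpha``, as candidate edges x -> y."""
    claims = build_basis_set(spec)
    added = []
    for claim in claims:
        p = _test_claim(data, claim, spec.groups, method=method)
        if p < alpha:
            added.append((claim[0], claim[1], p))
    return added


class PiecewiseSEM(BaseEstimator):
    """Directed-acyclic structural equation model with mixed components.

    Fitted attributes
    -----------------
    coefficients_ : per-edge estimates, standardized coefficients and p.
    claims_ : the d-separation basis set with per-claim p-values.
    fishers_c_, df_, pvalue_ : global goodness of fit.
    added_links_ : claims rejected at ``alpha`` (initially missing edges).
    """

    def __init__(self, spec=None, alpha=0.05, method="ai", tol=1e-8):
        self.spec = spec
        self.alpha = alpha
        self.method = method
        self.tol = tol

    def fit(self, data: pd.DataFrame):
        spec = self.spec if self.spec is not None else default_spec()
        self.spec_ = spec
        self.coefficients_ = fit_components(spec, data, method=self.method)
        claims = build_basis_set(spec)
        rows = []
        for claim in claims:
            p = _test_claim(data, claim, spec.groups, method=self.method)
            rows.append((claim[0], claim[1], "|".join(claim[2]), p))
        self.claims_ = pd.DataFrame(rows, columns=["x", "y", "conditioning", "p"])
        self.fishers_c_, self.df_, self.pvalue_ = fishers_c(self.claims_["p"])
        self.added_links_ = [
            (r.x, r.y, r.p) for r in self.claims_.itertuples() if r.p < self.alpha
        ]
        return self

    def to_dot(self):
        """DOT source of the fitted graph (solid = specified, dashed = added)."""
        lines = ["digraph sem {"]
        for r in self.coefficients_.itertuples():
            style = "solid" if r.p < self.alpha else "dotted"
            lines.append(
                f'  "{r.source}" -> "{r.target}" [label="{r.std_coef:.2f}", style={style}];'
            )
        for x, y, _ in self.added_links_:
            lines.append(f'  "{x}" -> "{y}" [style=dashed];')
        lines.append("}")
        return "\n".join(lines)
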