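"""Individual-tree animal models and trait summaries.

The animal model treats every tree's additive genetic value as a random
effect whose covariance is proportional to a relationship matrix (pedigree A
or genomic G), alongside random block and set-within-block design effects
and a fixed provenance/overall-mean structure:

    trait = mu + Provenance + Block + Block:Set + additive + residual

Variance components are estimated by EM-REML with an average-information
round for standard errors (see :mod:`droughtring.reml`); heritability uses
the full-denominator form

    h2 = sigma_a2 / (sigma_a2 + sigma_Block2 + sigma_Block:Set2 + sigma_e2)

with the conventional additive/(additive+residual) ratio available behind a
flag.  Bivariate fits yield additive covariances, hence genetic correlations
r = sigma_a,ij / sqrt(sigma_a2,i * sigma_a2,j), declared significant when
|r| exceeds twice its delta-method standard error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .reml import REMLProblem

__all__ = [
    "AnimalModel",
    "BivariateAnimalModel",
    "fit_animal_model",
    "heritability",
    "genetic_correlation",
    "emmeans_tukey",
    "NormalityTransformer",
    "normalize_transform",
    "phenotypic_correlations",
]

log = logging.getLogger(__name__)


def _dummies(col: pd.Series):
    levels = sorted(pd.unique(col.astype(str)))
    Z = np.zeros((len(col), len(levels)))
    lut = {l: k for k, l in enumerate(levels)}
    for i, v in enumerate(col.astype(str)):
        Z[i, lut[v]] = 1.0
    return Z, levels


def _fixed_design(data, fixed_effects):
    """Intercept plus treatment-coded dummies for each categorical factor."""
    cols = [np.ones((len(data), 1))]
    names = ["(mu)"]
    for f in fixed_effects:
        Z, levels = _dummies(data[f])
        cols.append(Z[:, 1:])  # drop first level
        names.extend(f"{f}[{l}]" for l in levels[1:])
    return np.hstack(cols), names


class AnimalModel(BaseEstimator):
    """Univariate animal model fitted by EM-REML (+ one AI round for SEs).

    Parameters
    ----------
    trait : response column name.
    relationship : DataFrame relationship matrix (A or G) indexed by id,
        covering at least every phenotyped individual; extra ids (parents)
        receive breeding values by back-solving.
    id_col : column linking data rows to the relationship matrix.
    fixed_effects : categorical fixed-effect columns (besides the mean).
    random_effects : categorical design random-intercept columns.
    denominator : "as-printed" (additive + block + set + residual) or
        "conventional" (additive + residual) heritability denominator.

    Fitted attributes: ``varcomp_`` (with SEs), ``heritability_``,
    ``heritability_se_``, ``breeding_values_`` (every id in the relationship
    matrix), ``beta_``, ``loglik_path_``, ``result_``.
    """

    def __init__(
        self,
        trait,
        relationship=None,
        id_col="tree_id",
        fixed_effects=(),
        random_effects=("block_id", "set_id"),
        denominator="as-printed",
        tol=1e-8,
        max_iter=1000,
        method="em",
        ai_rounds=1,
    ):
        self.trait = trait
        self.relationship = relationship
        self.id_col = id_col
        self.fixed_effects = fixed_effects
        self.random_effects = random_effects
        self.denominator = denominator
        self.tol = tol
        self.max_iter = max_iter
        self.method = method
        self.ai_rounds = ai_rounds

    # -- shared helpers (also used by the bivariate subclass) --------------

    def _prepare(self, data, traits):
        cols = [self.id_col, *traits, *self.fixed_effects, *self.random_effects]
        d = data[cols].dropna().reset_index(drop=True)
        if self.relationship is None:
            raise ValueError("a relationship matrix is required")
        ids = d[self.id_col].tolist()
        missing = [i for i in ids if i not in self.relationship.index]
        if missing:
            raise ValueError(f"relationship matrix lacks ids, e.g. {missing[:3]}")
        K = self.relationship.loc[ids, ids].to_numpy()
        X, xnames = _fixed_design(d, self.fixed_effects)
        factors = []
        for f in self.random_effects:
            Z, _ = _dummies(d[f])
            factors.append((f, Z))
        return d, ids, K, X, xnames, factors

    def _solve_bvs(self, ids, Py, Ga):
        """Back-solve BLUP breeding values for every id in the matrix."""
        Afull = self.relationship
        cross = Afull.loc[:, ids].to_numpy()
        U = cross @ Py @ np.atleast_2d(Ga)
        return pd.DataFrame(U, index=Afull.index)

    def fit(self, data: pd.DataFrame):
        d, ids, K, X, xnames, factors = self._prepare(data, [self.trait])
        prob = REMLProblem(d[self.trait].to_numpy(), X, kernel=K, factors=factors)
        res = prob.fit(method=self.method, tol=self.tol, max_iter=self.max_iter,
                       ai_rounds=self.ai_rounds)
        self.result_ = res
        self.n_obs_ = len(d)
        self.loglik_path_ = res.loglik_path
        self.beta_ = pd.Series(res.beta, index=xnames)
        vc = {"additive": float(res.G_a[0, 0]), "residual": float(res.R[0, 0])}
        se = {"additive": res.se[("Ga", 0, 0)], "residual": res.se[("R", 0, 0)]}
        for f in self.random_effects:
            vc[f] = float(res.factor_variances[f][0])
            se[f] = res.se[("F", f, 0)]
        self.varcomp_ = vc
        self.varcomp_se_ = se
        h2, h2se = heritability(res, denominator=self.denominator)
        self.heritability_ = h2
        self.heritability_se_ = h2se
        bv = self._solve_bvs(ids, res.Py, res.G_a[0, 0])
        self.breeding_values_ = bv[0].rename(self.trait)
        return self

    def predict(self, ids):
        """BLUP breeding values for the requested ids."""
        return self.breeding_values_.reindex(ids)


class BivariateAnimalModel(AnimalModel):
    """Bivariate animal model for additive genetic correlations.

    ``traits`` is a pair of response columns measured on the same trees.
    Design random effects get trait-specific variances; the additive and
    residual components are full 2x2 covariance matrices.

    Fitted attributes: ``G_a_``, ``R_``, ``genetic_correlation_``,
    ``genetic_correlation_se_``, ``significant_`` (|r| > 2 SE), plus
    ``breeding_values_`` with one column per trait.
    """

    def __init__(
        self,
        traits,
        relationship=None,
        id_col="tree_id",
        fixed_effects=(),
        random_effects=("block_id", "set_id"),
        tol=1e-8,
        max_iter=1000,
        method="em",
        ai_rounds=1,
    ):
        super().__init__(
            trait=None,
            relationship=relationship,
            id_col=id_col,
            fixed_effects=fixed_effects,
            random_effects=random_effects,
            tol=tol,
            max_iter=max_iter,
            method=method,
            ai_rounds=ai_rounds,
        )
        self.traits = tuple(traits)

    def fit(self, data: pd.DataFrame):
        d, ids, K, X, xnames, factors = self._prepare(data, list(self.traits))
        Y = d[list(self.traits)].to_numpy()
        prob = REMLProblem(Y, X, kernel=K, factors=factors)
        res = prob.fit(method=self.method, tol=self.tol, max_iter=self.max_iter,
                       ai_rounds=self.ai_rounds)
        self.result_ = res
        self.n_obs_ = len(d)
        self.loglik_path_ = res.loglik_path
        self.G_a_ = res.G_a
        self.R_ = res.R
        r, rse = genetic_correlation(res)
        self.genetic_correlation_ = r
        self.genetic_correlation_se_ = rse
        self.significant_ = (r is not None) and (rse is not None) and abs(r) > 2 * rse
        bv = self._solve_bvs(ids, res.Py, res.G_a)
        bv.columns = list(self.traits)
        self.breeding_values_ = bv
        return self


def fit_animal_model(data, trait, relationship, tol=1e-8, max_iter=1000, **kwargs):
    """Functional wrapper: returns (varcomp dict with SEs, breeding values)."""
    m = AnimalModel(trait=trait, relationship=relationship, tol=tol,
                    max_iter=max_iter, **kwargs).fit(data)
    vc = {k: (m.varcomp_[k], m.varcomp_se_[k]) for k in m.varcomp_}
    return vc, m.breeding_values_


def heritability(result, denominator="as-printed"):
    """Narrow-sense heritability and its delta-method SE from a REML fit.

    With the full denominator, h2 = sa / (sa + s_block + s_set + se) where
    the design variances are all fitted design random effects; the
    conventional variant uses sa / (sa + se).
    """
    if result.G_a is None:
        raise ValueError("fit has no additive component")
    labels = result.param_labels
    theta = []
    use = []
    for i, lab in enumerate(labels):
        if lab == ("Ga", 0, 0):
            theta.append(result.G_a[0, 0]); use.append(i)
        elif lab == ("R", 0, 0):
            theta.append(result.R[0, 0]); use.append(i)
        elif lab[0] == "F" and denominator == "as-printed":
            theta.append(result.factor_variances[lab[1]][lab[2]]); use.append(i)
    theta = np.array(theta)
    total = theta.sum()
    if total <= 0:
        raise ValueError("all variance components are zero")
    sa = result.G_a[0, 0]
    h2 = sa / total
    grad = np.full(len(theta), -sa / total**2)
    grad[0] += 1.0 / total
    cov = result.cov_params[np.ix_(use, use)]
    var = float(grad @ cov @ grad)
    return float(h2), float(np.sqrt(max(var, 0.0)))


def genetic_correlation(result):
    """Additive correlation r = sa_ij / sqrt(sa_ii sa_jj) with delta SE.

    Returns (None, None) when either additive variance sits at the boundary
    (the correlation is then undefined).
    """
    Ga = result.G_a
    if Ga is None or Ga.shape[0] < 2:
        raise ValueError("needs a bivariate fit")
    v1, c, v2 = Ga[0, 0], Ga[0, 1], Ga[1, 1]
    floor = 1e-8 * max(np.diag(result.R).max(), 1e-300)
    if v1 <= floor or v2 <= floor:
        log.warning("additive variance at boundary: genetic correlation undefined")
        return None, None
    r = c / np.sqrt(v1 * v2)
    labels = result.param_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    use = [idx[("Ga", 0, 0)], idx[("Ga", 0, 1)], idx[("Ga", 1, 1)]]
    grad = np.array([-r / (2 * v1), 1.0 / np.sqrt(v1 * v2), -r / (2 * v2)])
    cov = result.cov_params[np.ix_(use, use)]
    var = float(grad @ cov @ grad)
    return float(r), float(np.sqrt(max(var, 0.0)))


# ------------------------------------------------------------------ site EMMs


def _letters_from_pairs(names, sig_pairs):
    """Compact letter display: insert-and-absorb over significant pairs."""
    cols = [set(names)]
    for i, j in sig_pairs:
        for c in [c for c in cols if i in c and j in c]:
            cols.remove(c)
            a, b = c - {i}, c - {j}
            for new in (a, b):
                if not any(new <= other for other in cols):
                    cols.append(new)
    cols = [c for c in cols if c]
    cols.sort(key=lambda c: min(names.index(x) for x in c))
    letters = {n: "" for n in names}
    for k, c in enumerate(cols):
        for n in c:
            letters[n] += chr(ord("a") + k)
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def emmeans_tukey(data, trait, site_col="site", random_effects=("block_id", "set_id"),
                  alpha=0.05, method="ai", tol=1e-8):
    """Estimated marginal site means with Tukey-adjusted pairwise contrasts.

    Fits trait = Site (fixed, cell means) + design random intercepts +
    residual by REML; the EMMs are the fixed site coefficients.  All
    pairwise differences are tested against the studentized range
    distribution (residual/containment degrees of freedom), and a compact
    letter display summarizes the groups, ordered by descending mean.
    Sites with fewer than 2 observations are dropped with a warning.
    """
    d = data[[trait, site_col, *random_effects]].dropna().reset_index(drop=True)
    counts = d[site_col].value_counts()
    bad = counts[counts < 2].index.tolist()
    if bad:
        log.warning("dropping sites with <2 observations: %s", bad)
        d = d[~d[site_col].isin(bad)].reset_index(drop=True)
    sites = sorted(d[site_col].unique())
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    Xs, _ = _dummies(d[site_col])
    factors = [(f, _dummies(d[f])[0]) for f in random_effects]
    prob = REMLProblem(d[trait].to_numpy(), Xs, factors=factors)
    res = prob.fit(method=method, tol=tol, max_iter=500)
    emm = res.beta
    C = res.cov_beta
    k = len(sites)
    df = len(d) - k
    rows = []
    sig_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = emm[i] - emm[j]
            sed = np.sqrt(C[i, i] + C[j, j] - 2 * C[i, j])
            q = abs(diff) / sed * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df))
            rows.append((sites[i], sites[j], diff, sed, p))
            if p < alpha:
                sig_pairs.append((sites[i], sites[j]))
    contrasts = pd.DataFrame(rows, columns=["site_a", "site_b", "diff", "se", "p_tukey"])
    order = list(np.array(sites)[np.argsort(-emm)])
    letters = _letters_from_pairs(order, sig_pairs)
    means = pd.DataFrame({
        "site": sites,
        "emmean": emm,
        "se": np.sqrt(np.diag(C)),
        "letters": [letters[s] for s in sites],
    })
    return means, contrasts


# ---------------------------------------------------------------- transforms


class NormalityTransformer(BaseEstimator, TransformerMixin):
    """Pick none / sqrt / log to normalize a positive-skewed trait.

    The raw values are first screened with D'Agostino's normality test; if
    they pass (p > alpha) no transform is applied.  Otherwise the transform
    minimizing |sample skewness| among the domain-valid candidates is chosen
    (log needs strictly positive values and falls back to sqrt otherwise).
    """

    def __init__(self, alpha=0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if len(x) < 8 or np.ptp(x) == 0:
            self.transform_ = "none"
            self.skewness_ = 0.0
            return self
        try:
            p_norm = stats.normaltest(x).pvalue
        except ValueError:
            p_norm = 1.0
        if p_norm > self.alpha:
            self.transform_ = "none"
            self.skewness_ = float(stats.skew(x))
            return self
        candidates = {"none": x}
        if (x >= 0).all():
            candidates["sqrt"] = np.sqrt(x)
        if (x > 0).all():
            candidates["log"] = np.log(x)
        skews = {k: abs(float(stats.skew(v))) for k, v in candidates.items()}
        self.transform_ = min(skews, key=skews.get)
        self.skewness_ = skews[self.transform_]
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=float)
        if self.transform_ == "sqrt":
            return np.sqrt(x)
        if self.transform_ == "log":
            if (x <= 0).any():
                log.warning("non-positive values under log transform; using sqrt")
                return np.sqrt(np.clip(x, 0, None))
            return np.log(x)
        return x


def normalize_transform(values, alpha=0.05):
    """Functional wrapper: returns (transformed values, chosen transform)."""
    t = NormalityTransformer(alpha=alpha).fit(values)
    return t.transform(values), t.transform_


# -------------------------------------------------------------- correlations


def phenotypic_correlations(trait_table: pd.DataFrame, traits=None, min_pairs=3):
    """Pairwise-complete Pearson correlations with Bonferroni-adjusted p.

    Returns (r, p_raw, p_adj) DataFrames; the adjustment multiplies each raw
    p by the number of tested pairs, capped at 1.  Cells with fewer than
    ``min_pairs`` complete pairs or zero variance are NaN.
    """
    if traits is None:
        traits = [c for c in trait_table.columns if pd.api.types.is_numeric_dtype(trait_table[c])]
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    tested = 0
    for i in range(k):
        for j in range(i + 1, k):
            sub = trait_table[[traits[i], traits[j]]].dropna()
            if len(sub) < min_pairs or sub.iloc[:, 0].std() == 0 or sub.iloc[:, 1].std() == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
            tested += 1
    p_adj = (p * tested).clip(upper=1.0)
    np.fill_diagonal(p_adj.values, 0.0)
    return r, p, p_adj
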