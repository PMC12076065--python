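"""Synthetic progeny-trial study generator with known ground truth.

Emulates a half-sib conifer progeny trial: several test sites, each planting
open-pollinated (OP) families divided into sets, with each set randomized in
blocks as four-tree family row plots on a square grid.  Families are treated
as maternal half-sib groups (seed parent known, pollen parents unknown), so
the expected additive relationship is 0.25 within a family.

The generator produces the layout, monthly climate with forced drought years,
a pedigree with true breeding values (gene dropping), SNP dosages, annual
ring-width series shaped by an age trend, drought events, competition and
lognormal noise, and the associated tree-level traits (height, DBH, gall-rust
score, delta13C, wood density).  Everything flows from one seed through
``numpy.random.SeedSequence`` spawning, so a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ClimateTable, DensityProfile, RingSeries, TruthRecord

__all__ = [
    "simulate_design",
    "simulate_climate",
    "build_op_pedigree",
    "simulate_genetics",
    "simulate_snps",
    "GrowthParams",
    "simulate_growth",
    "simulate_density_profile",
    "hargreaves_pet",
    "DEFAULT_SITES",
]

DEFAULT_SITES = ["JUDY", "SWAN", "TIME", "VIRG"]


def _rng(seed):
    return np.random.default_rng(seed)


# --------------------------------------------------------------------- design


def simulate_design(
    n_sites=4,
    n_families=224,
    n_sets=19,
    n_blocks=5,
    plot_size=4,
    spacing_m=2.5,
    mortality_rate=0.0,
    seed=None,
    site_names=None,
):
    """Randomized sets-in-blocks layout with family row plots.

    Families are partitioned into ``n_sets`` near-equal sets; each set is
    planted in every block, with a random family-to-plot order per set-block.
    Each plot is ``plot_size`` trees in a row at ``spacing_m`` spacing, so a
    family contributes ``n_blocks * plot_size`` trees per site (20 under the
    default 5 blocks x 4 trees).

    Returns a tidy DataFrame: site, block, set, plot, family, tree_id,
    row, col, x_m, y_m, alive.
    """
    for name, v in [("n_sites", n_sites), ("n_families", n_families),
                    ("n_sets", n_sets), ("n_blocks", n_blocks), ("plot_size", plot_size)]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if not (0.0 <= mortality_rate < 1.0):
        raise ValueError("mortality_rate must be in [0, 1)")
    if n_families < n_sets:
        raise ValueError(
            f"cannot divide {n_families} families into {n_sets} sets: "
            "need at least one family per set"
        )
    if site_names is None:
        site_names = (DEFAULT_SITES * math.ceil(n_sites / len(DEFAULT_SITES)))[:n_sites]
    rng = _rng(seed)

    families = [f"F{j+1:03d}" for j in range(n_families)]
    # near-equal partition of families into sets (sizes differ by at most 1)
    bounds = np.linspace(0, n_families, n_sets + 1).round().astype(int)
    set_of = {}
    for s in range(n_sets):
        for f in families[bounds[s]:bounds[s + 1]]:
            set_of[f] = s + 1
    fams_in_set = {s: [f for f in families if set_of[f] == s] for s in range(1, n_sets + 1)}

    plots_per_row = 8  # plots laid side by side; purely geometric choice
    rows = []
    for site in site_names:
        row0 = 0
        for b in range(1, n_blocks + 1):
            plot_counter = 0
            for s in range(1, n_sets + 1):
                fams = list(fams_in_set[s])
                rng.shuffle(fams)
                for fam in fams:
                    prow = row0 + plot_counter // plots_per_row
                    pcol0 = (plot_counter % plots_per_row) * plot_size
                    for k in range(plot_size):
                        rows.append((site, b, s, plot_counter, fam, prow, pcol0 + k))
                    plot_counter += 1
            row0 += math.ceil(plot_counter / plots_per_row)
    df = pd.DataFrame(rows, columns=["site", "block", "set", "plot", "family", "row", "col"])
    df["tree_id"] = (
        df["site"] + "_" + df["block"].astype(str) + "_" + df["family"]
        + "_" + df.groupby(["site", "block", "family"]).cumcount().add(1).astype(str)
    )
    df["x_m"] = df["col"] * spacing_m
    df["y_m"] = df["row"] * spacing_m
    df["alive"] = rng.random(len(df)) >= mortality_rate if mortality_rate > 0 else True
    return df


# -------------------------------------------------------------------- climate


def _extraterrestrial_radiation(latitude_deg, month):
    """FAO-56 daily extraterrestrial radiation (MJ m-2 day-1), mid-month."""
    doy = int(30.4 * month - 15)
    lat = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(lat) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (24 * 60 / math.pi) * 0.0820 * dr * (
        ws * math.sin(lat) * math.sin(delta) + math.cos(lat) * math.cos(delta) * math.sin(ws)
    )
    return max(ra, 0.0)


_DAYS = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def hargreaves_pet(tmean, tmin, tmax, latitude_deg, month, coef=0.0023):
    """Hargreaves (1985) monthly reference evapotranspiration in mm.

    PET = coef * Ra * (T + 17.8) * sqrt(Tmax - Tmin) per day, with Ra the
    extraterrestrial radiation converted to its evaporation equivalent
    (0.408 mm per MJ m-2).  Negative (T + 17.8) or inverted diurnal ranges
    contribute zero.  ``coef`` is the Hargreaves coefficient; the original
    0.0023 is the default, but regional recalibration is common practice and
    the boreal-foothills water balance (moisture index ~ +130 mm in normal
    years at ~535 mm precipitation) needs a smaller value.
    """
    ra = _extraterrestrial_radiation(latitude_deg, month) * 0.408
    trange = max(float(tmax) - float(tmin), 0.0)
    pet_day = coef * ra * max(float(tmean) + 17.8, 0.0) * math.sqrt(trange)
    return pet_day * _DAYS[month - 1]


# seasonal shape for precipitation: continental summer-wet regime
_PRECIP_W = np.array([0.04, 0.035, 0.045, 0.055, 0.09, 0.14, 0.17, 0.13, 0.09, 0.07, 0.065, 0.07])
_PRECIP_W = _PRECIP_W / _PRECIP_W.sum()


def simulate_climate(
    years=range(1982, 2017),
    drought_years=(2002, 2010),
    seed=None,
    latitude=54.5,
    mat=2.4,
    seasonal_amplitude=14.5,
    annual_precip=535.0,
    year_sd=0.12,
    drought_precip_ratio=0.75,
    hargreaves_coef=0.0013,
):
    """Monthly climate with a climate moisture index forced negative in
    drought years.

    CMI = annual precipitation - annual Hargreaves PET.  In drought years the
    year's precipitation is rescaled to ``drought_precip_ratio`` x PET so the
    annual CMI is negative by construction (as diagnosed from the observed
    record, where drought events show CMI < 0).
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    drought_years = set(drought_years)
    if not drought_years <= set(years):
        raise ValueError("drought_years must be a subset of years")
    rng = _rng(seed)

    recs = []
    for year in years:
        tshift = rng.normal(0.0, 0.7)
        pfac = math.exp(rng.normal(0.0, year_sd))
        months = []
        for m in range(1, 13):
            tm = mat - seasonal_amplitude * math.cos(2 * math.pi * (m - 1) / 12.0) + tshift \
                + rng.normal(0.0, 0.8)
            tmin = tm - 6.5 + rng.normal(0.0, 0.4)
            tmax = tm + 6.5 + rng.normal(0.0, 0.4)
            pr = annual_precip * _PRECIP_W[m - 1] * pfac * math.exp(rng.normal(0.0, 0.25))
            months.append([year, m, tm, tmin, tmax, pr])
        pet = sum(hargreaves_pet(r[2], r[3], r[4], latitude, r[1], coef=hargreaves_coef)
                  for r in months)
        if year in drought_years:
            target = drought_precip_ratio * pet
            cur = sum(r[5] for r in months)
            for r in months:
                r[5] *= target / cur
        recs.extend(months)

    monthly = pd.DataFrame(recs, columns=["year", "month", "tmean", "tmin", "tmax", "precip"])
    ann = []
    for year, g in monthly.groupby("year"):
        pet = sum(
            hargreaves_pet(r.tmean, r.tmin, r.tmax, latitude, int(r.month), coef=hargreaves_coef)
            for r in g.itertuples()
        )
        p = g["precip"].sum()
        ann.append((year, p, pet, p - pet))
    annual = pd.DataFrame(ann, columns=["year", "precip", "pet", "cmi"])
    return ClimateTable(monthly=monthly, annual=annual, latitude=latitude)


# ------------------------------------------------------------------- pedigree


def build_op_pedigree(layout, contamination_rate=0.0, seed=None):
    """Pedigree for an open-pollinated trial from a layout table.

    Each family's seed parent (dam) is a founder; every offspring has an
    unknown, unrelated sire (true half-sibs).  With ``contamination_rate`` > 0
    a fraction of offspring keep their recorded family label but actually
    descend from a different dam ("pollen/seed-lot contamination"), to
    exercise genomic pedigree correction.

    Returns a DataFrame: id, dam (recorded), sire, family (recorded label),
    true_family, true_dam; dams are listed first (founders, both parents
    unknown).  Analyses should use the recorded columns; the generator uses
    the true ones.
    """
    rng = _rng(seed)
    fams = sorted(layout["family"].unique())
    dam_of = {f: f"DAM_{f}" for f in fams}
    rows = [(dam_of[f], None, None, f, f, None) for f in fams]
    offspring = layout["tree_id"].tolist()
    rec_fam = layout["family"].tolist()
    n_bad = int(round(contamination_rate * len(offspring)))
    bad = set(rng.choice(len(offspring), size=n_bad, replace=False)) if n_bad else set()
    for i, (tid, fam) in enumerate(zip(offspring, rec_fam)):
        true_fam = fam
        if i in bad:
            others = [f for f in fams if f != fam]
            true_fam = others[rng.integers(len(others))]
        rows.append((tid, dam_of[fam], None, fam, true_fam, dam_of[true_fam]))
    ped = pd.DataFrame(rows, columns=["id", "dam", "sire", "family", "true_family", "true_dam"])
    # founders' true_dam stays missing
    ped.loc[ped["true_dam"].isna() & ped["dam"].notna(), "true_dam"] = ped["dam"]
    return ped


# ------------------------------------------------------------------- genetics


def _check_psd(R, name="genetic correlation matrix"):
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})")
    return R


def simulate_genetics(
    pedigree,
    trait_specs,
    r_g=None,
    seed=None,
    parent_elevation=None,
    elevation_beta=None,
):
    """Gene-drop true breeding values through a pedigree.

    trait_specs: dict trait -> dict(sigma_a2, sigma_block2, sigma_set2,
    sigma_e2); variances must be non-negative.  r_g is the true additive
    correlation matrix across traits (identity by default; must be PSD).

    Founder BVs are multivariate normal with covariance
    ``D^(1/2) r_g D^(1/2)`` (D = additive variances).  An offspring inherits
    half of each known parent's BV plus a Mendelian deviation; an unknown
    parent contributes an independent draw of half a founder BV, so offspring
    of one dam with unknown unrelated sires are exact maternal half-sibs
    (BV covariance sigma_a2 / 4).

    ``parent_elevation``/``elevation_beta`` inject a local-adaptation cline:
    founder dam BVs gain ``beta * (elev - mean elev)`` for the listed traits.
    """
    traits = list(trait_specs)
    T = len(traits)
    for tr, sp in trait_specs.items():
        for key in ("sigma_a2", "sigma_block2", "sigma_set2", "sigma_e2"):
            if sp.get(key, 0.0) < 0:
                raise ValueError(f"negative variance {key} for trait {tr}")
    if r_g is None:
        r_g = np.eye(T)
    r_g = _check_psd(np.asarray(r_g, dtype=float))
    sa = np.array([math.sqrt(trait_specs[t]["sigma_a2"]) for t in traits])
    Sigma = (sa[:, None] * r_g) * sa[None, :]
    # PSD square root (Cholesky fails for sigma_a2 = 0 or r_g on the boundary)
    w, Q = np.linalg.eigh(Sigma)
    Lr = Q * np.sqrt(np.clip(w, 0.0, None))

    rng = _rng(seed)
    ped = pedigree.reset_index(drop=True)
    ids = ped["id"].tolist()
    dam_col = "true_dam" if "true_dam" in ped.columns else "dam"
    idx = {i: k for k, i in enumerate(ids)}
    bv = np.zeros((len(ids), T))
    elev_adj = {}
    if parent_elevation is not None and elevation_beta:
        elev = pd.Series(parent_elevation)
        cent = elev - elev.mean()
        for j, tr in enumerate(traits):
            beta = elevation_beta.get(tr, 0.0)
            if beta:
                for pid, e in cent.items():
                    elev_adj.setdefault(pid, np.zeros(T))[j] = beta * e

    for k, row in enumerate(ped.itertuples()):
        dam = getattr(row, dam_col)
        sire = row.sire
        dam_known = isinstance(dam, str) and dam in idx
        sire_known = isinstance(sire, str) and sire in idx
        if not dam_known and not sire_known and pd.isna(dam) and pd.isna(sire):
            # founder
            bv[k] = Lr @ rng.standard_normal(T)
            if row.id in elev_adj:
                bv[k] += elev_adj[row.id]
            continue
        contrib = np.zeros(T)
        var_scale = 0.5  # Mendelian sampling variance (both parents known)
        for parent, known in ((dam, dam_known), (sire, sire_known)):
            if known:
                contrib += 0.5 * bv[idx[parent]]
            else:
                var_scale += 0.25  # unknown unrelated parent: +Sigma/4
        bv[k] = contrib + math.sqrt(var_scale) * (Lr @ rng.standard_normal(T))

    bv_df = pd.DataFrame(bv, index=ids, columns=traits)
    variances = {t: dict(trait_specs[t]) for t in traits}
    return TruthRecord(
        traits=traits,
        variances=variances,
        breeding_values=bv_df,
        genetic_correlation=pd.DataFrame(r_g, index=traits, columns=traits),
        parent_elevation=pd.Series(parent_elevation) if parent_elevation is not None else None,
        elevation_beta=dict(elevation_beta or {}),
    )


def simulate_snps(pedigree, n_snps=500, maf_range=(0.1, 0.5), missing_rate=0.0, seed=None):
    """Biallelic dosage matrix (0/1/2) by Mendelian gene dropping.

    Founders are drawn from Hardy-Weinberg proportions at per-locus minor
    allele frequencies sampled uniformly from ``maf_range``; an offspring
    receives one allele from each parent (Bernoulli(dosage/2) transmission for
    unlinked loci), with unknown parents replaced by a population draw.
    Missing entries (NaN) are masked at ``missing_rate``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, n_snps)
    ped = pedigree.reset_index(drop=True)
    dam_col = "true_dam" if "true_dam" in ped.columns else "dam"
    ids = ped["id"].tolist()
    idx = {i: k for k, i in enumerate(ids)}
    M = np.zeros((len(ids), n_snps), dtype=float)
    for k, row in enumerate(ped.itertuples()):
        dam = getattr(row, dam_col)
        sire = row.sire
        alleles = np.zeros(n_snps)
        for parent in (dam, sire):
            if isinstance(parent, str) and parent in idx:
                alleles += rng.random(n_snps) < (M[idx[parent]] / 2.0)
            else:
                alleles += rng.random(n_snps) < p
        M[k] = alleles
    geno = pd.DataFrame(M, index=ids, columns=[f"snp{j+1}" for j in range(n_snps)])
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno = geno.mask(mask)
    return geno


# --------------------------------------------------------------------- growth


@dataclass
class GrowthParams:
    """Tunables of the generative ring-width model.

    Ring width (mm) for tree i in calendar year y is

        w = w_max * hump(age) * site_mult * drought_mult * comp_mult * noise

    hump(age) = ((age/age_peak) * exp(1 - age/age_peak))^age_shape is a
    Hugershoff-type age trend peaking (at 1.0) near the 1997-2001
    maximum-growth window for a 1982 planting.  In a drought event year the log width drops by
    (event_depth - g_resist); for the 4 post-event years it drops by
    recovery_base * recovery_decay^(k-1) * deficit and, permanently, by
    persist_coef * deficit per event, where
    deficit = recovery_depth - g_recov + rust_gamma * rust_latent
    couples slow recovery, long-term decline and gall-rust damage.
    """

    w_max: float = 3.2
    age_peak: float = 17.0
    age_shape: float = 1.0
    site_mult: dict = field(default_factory=dict)  # site -> multiplier
    event_depth: float = 0.35
    recovery_depth: float = 0.32
    recovery_base: float = 0.60
    recovery_decay: float = 0.55
    persist_coef: float = 0.85
    event_env_sd: float = 0.15  # plastic (non-genetic) event-year response
    recovery_env_sd: float = 0.35  # plastic post-event recovery deficit
    dbh_noise_cm: float = 0.8  # DBH measurement error
    comp_coef: float = 0.25
    noise_sd: float = 0.10
    rust_gamma: float = 0.35
    rust_sd: float = 1.0
    rust_mu: float = 2.0
    rust_recov_loading: float = 1.2
    d13c_mu: float = -26.0
    d13c_sd: float = 0.5
    density_mu: float = 430.0
    density_sd: float = 25.0
    height_b: float = 55.0
    height_sd: float = 40.0
    neighbor_radius: float = 7.1


def _neighbor_counts(layout, radius):
    """Alive neighbours within ``radius`` m, per site."""
    from scipy.spatial import cKDTree

    counts = np.zeros(len(layout), dtype=int)
    for _, g in layout.groupby("site"):
        xy = g[["x_m", "y_m"]].to_numpy()
        alive = g["alive"].to_numpy()
        tree = cKDTree(xy[alive])
        hits = tree.query_ball_point(xy, r=radius)
        n_hits = np.array([len(h) for h in hits])
        counts[g.index.to_numpy()] = n_hits - alive.astype(int)  # drop self when alive
    return counts


def simulate_growth(layout, climate, truth, params=None, seed=None, drought_years=(2002, 2010)):
    """Generate ring-width series and tree-level traits for a layout.

    Requires ``truth`` to carry 'resist', 'recov', 'height', 'd13c',
    'density' breeding values for every tree in the layout.  Returns
    ``(series, traits)`` where series is a dict tree_id -> RingSeries for
    alive trees and traits is a tidy DataFrame (one row per alive tree).
    """
    params = params or GrowthParams()
    rng = _rng(seed)
    years = np.asarray(sorted(climate.annual["year"])) if climate is not None else np.arange(1982, 2017)
    if climate is not None:
        missing = set(drought_years) - set(years.tolist())
        if missing:
            raise ValueError(f"drought years {sorted(missing)} missing from climate table")
    lay = layout.reset_index(drop=True)
    alive = lay["alive"].to_numpy()
    n = len(lay)
    ids = lay["tree_id"].tolist()
    bv = truth.breeding_values
    need = ["resist", "recov", "height", "d13c", "density"]
    for tr in need:
        if tr not in bv.columns:
            raise ValueError(f"truth record lacks required trait '{tr}'")
    g = bv.reindex(ids)
    if g.isna().any().any():
        raise ValueError("truth record missing breeding values for some trees")

    ages = years - years.min() + 1
    hump = ((ages / params.age_peak) * np.exp(1 - ages / params.age_peak)) ** params.age_shape
    site_mult = np.array([params.site_mult.get(s, 1.0) for s in lay["site"]])

    nb = _neighbor_counts(lay, params.neighbor_radius)
    comp = nb / 24.0  # 24 = full two-rows/columns neighbourhood on the grid

    rust_latent = rng.normal(0.0, params.rust_sd, n) - params.rust_recov_loading * g["recov"].to_numpy()
    rust_score = np.clip(np.round(params.rust_mu + rust_latent), 0, 6).astype(int)
    rl_std = (rust_latent - rust_latent.mean()) / (rust_latent.std() + 1e-12)

    # persistent (long-term) deficit has its own genetic channel when the
    # truth record provides one; otherwise it shares the recovery genotype
    g_persist = g["persist"].to_numpy() if "persist" in g.columns else g["recov"].to_numpy()
    g_growth = g["growth"].to_numpy() if "growth" in g.columns else np.zeros(n)
    shared = (
        params.recovery_depth
        + params.rust_gamma * rl_std * 0.1
        + params.comp_coef * 0.3 * (comp - comp.mean())
    )

    logw = np.log(params.w_max) + np.log(hump)[None, :] + np.log(site_mult)[:, None]
    logw = logw - params.comp_coef * comp[:, None] + g_growth[:, None]
    for e in drought_years:
        ei = int(np.where(years == e)[0][0])
        eps_evt = rng.normal(0.0, params.event_env_sd, n) if params.event_env_sd > 0 else 0.0
        eps_rec = rng.normal(0.0, params.recovery_env_sd, n) if params.recovery_env_sd > 0 else 0.0
        deficit_rec = shared - g["recov"].to_numpy() + eps_rec
        deficit_per = shared - g_persist + eps_rec
        logw[:, ei] -= np.maximum(params.event_depth - g["resist"].to_numpy() + eps_evt, 0.0)
        for k in range(1, 5):
            if ei + k < len(years):
                logw[:, ei + k] -= params.recovery_base * params.recovery_decay ** (k - 1) * deficit_rec
        if ei + 1 < len(years):
            logw[:, ei + 1 :] -= params.persist_coef * deficit_per[:, None]
    if params.noise_sd > 0:
        logw += rng.normal(0.0, params.noise_sd, logw.shape)
    widths = np.exp(logw)

    series = {
        tid: RingSeries(tree_id=tid, first_year=int(years.min()), widths=widths[i])
        for i, tid in enumerate(ids)
        if alive[i]
    }

    radius = widths.sum(axis=1)  # mm at the end of the record
    dbh30 = 2 * widths[:, : min(30, widths.shape[1])].sum(axis=1) / 10.0  # cm
    dbh35 = 2 * radius / 10.0
    if params.dbh_noise_cm > 0:
        dbh30 = np.maximum(dbh30 + rng.normal(0.0, params.dbh_noise_cm, n), 0.5)
        dbh35 = np.maximum(dbh35 + rng.normal(0.0, params.dbh_noise_cm, n), 0.5)
    area35 = np.pi * radius**2
    height = (
        400.0
        + params.height_b * np.log1p(area35 / 100.0)
        + g["height"].to_numpy()
        + rng.normal(0.0, params.height_sd, n)
    )
    d13c = params.d13c_mu + g["d13c"].to_numpy() + rng.normal(0.0, params.d13c_sd, n)
    dens = params.density_mu + g["density"].to_numpy() + rng.normal(0.0, params.density_sd, n) \
        + 15.0 * comp
    traits = lay[["tree_id", "site", "block", "set", "plot", "family", "alive"]].copy()
    traits["n_neighbors"] = nb
    traits["gall_rust"] = rust_score
    traits["d13c"] = d13c
    traits["wood_density"] = dens
    traits["dbh30"] = dbh30
    traits["dbh35"] = dbh35
    traits["height35"] = height
    traits = traits[traits["alive"]].drop(columns="alive").reset_index(drop=True)
    return series, traits


# --------------------------------------------------------------- densitometry


def simulate_density_profile(
    ring_widths,
    step=0.0254,
    ew_density=350.0,
    lw_density=650.0,
    noise_sd=0.0,
    ew_fraction=0.6,
    seed=None,
    tree_id="sim",
):
    """Piecewise-constant earlywood/latewood density profile for given rings.

    Each ring spans ``round(width / step)`` samples: an earlywood plateau
    followed by a latewood plateau, with the sharp latewood-to-earlywood drop
    marking the ring boundary.  Gaussian noise of ``noise_sd`` kg/m3 is added.
    Rings narrower than two sampling steps are rejected.
    """
    widths = np.asarray(ring_widths, dtype=float)
    if np.any(widths <= step):
        raise ValueError("all ring widths must exceed the sampling step")
    n_samp = np.round(widths / step).astype(int)
    if np.any(n_samp < 2):
        raise ValueError("ring narrower than 2 sampling steps")
    dens = []
    for ns in n_samp:
        n_ew = max(1, int(round(ew_fraction * ns)))
        n_ew = min(n_ew, ns - 1)
        dens.append(np.concatenate([np.full(n_ew, ew_density), np.full(ns - n_ew, lw_density)]))
    density = np.concatenate(dens)
    if noise_sd > 0:
        density = density + _rng(seed).normal(0.0, noise_sd, len(density))
    positions = np.arange(len(density)) * step
    return DensityProfile(
        tree_id=tree_id,
        positions=positions,
        density=density,
        step=step,
        true_widths=n_samp * step,
    )
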