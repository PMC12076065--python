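"""End-to-end driver: simulate a study, run every analysis stage, write a
report.

Stages: synth -> densitometry -> rings -> kinship -> lmm -> sem -> adapt.
Any stage failure aborts with the stage name; a fixed seed makes the whole
run deterministic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import adapt as adapt_mod
from . import densitometry, kinship, rings, synth
from .io import RunConfig, ring_series_to_frame, write_rwl, write_truth_json
from .lmm import AnimalModel, BivariateAnimalModel, emmeans_tukey
from .sem import PiecewiseSEM, default_spec

log = logging.getLogger(__name__)

INDEX_TRAITS = [
    "decline",
    "resilience_2002",
    "resilience_2010",
    "resistance_2002",
    "resistance_2010",
    "height35",
    "dbh35",
]


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def default_trait_specs():
    """True simulation variances for the genetic architecture.

    'resist' and 'recov' act on the log ring-width scale; 'height' (cm),
    'd13c' (permil) and 'density' (kg/m3) act on the trait scale.
    """
    return {
        "resist": dict(sigma_a2=0.0064, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
        "recov": dict(sigma_a2=0.0225, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
        "persist": dict(sigma_a2=0.0225, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
        "growth": dict(sigma_a2=0.003, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
        "height": dict(sigma_a2=900.0, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
        "d13c": dict(sigma_a2=0.09, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
        "density": dict(sigma_a2=300.0, sigma_block2=0.0, sigma_set2=0.0, sigma_e2=0.0),
    }


DEFAULT_RG = np.array(
    [
        # resist recov persist growth height d13c density
        [1.00, 0.30, 0.25, 0.10, 0.10, 0.00, 0.00],
        [0.30, 1.00, 0.80, 0.30, 0.30, 0.00, 0.00],
        [0.25, 0.80, 1.00, 0.30, 0.30, 0.00, 0.00],
        [0.10, 0.30, 0.30, 1.00, 0.50, 0.00, 0.00],
        [0.10, 0.30, 0.30, 0.50, 1.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.10],
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.10, 1.00],
    ]
)

# lower elevation of origin -> better drought recovery and persistence
ELEVATION_BETA = {"recov": -5.5e-4, "persist": -5.5e-4}


def simulate_study(cfg: RunConfig):
    """Generate the full synthetic study; returns a dict of artifacts."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(8)
    layout = synth.simulate_design(
        n_sites=cfg.n_sites,
        n_families=cfg.n_families,
        n_sets=cfg.n_sets,
        n_blocks=cfg.n_blocks,
        plot_size=cfg.plot_size,
        spacing_m=cfg.spacing_m,
        mortality_rate=cfg.mortality_rate,
        seed=seeds[0],
    )
    climate = synth.simulate_climate(
        years=range(cfg.years[0], cfg.years[1] + 1),
        drought_years=cfg.drought_years,
        seed=seeds[1],
    )
    pedigree = synth.build_op_pedigree(
        layout, contamination_rate=cfg.contamination_rate, seed=seeds[2]
    )
    rng = np.random.default_rng(seeds[3])
    lo, hi = cfg.elevation_range
    dams = pedigree[pedigree["dam"].isna()]["id"]
    elevation = pd.Series(rng.uniform(lo, hi, len(dams)), index=dams)
    truth = synth.simulate_genetics(
        pedigree,
        default_trait_specs(),
        r_g=DEFAULT_RG,
        seed=seeds[4],
        parent_elevation=elevation,
        elevation_beta=ELEVATION_BETA,
    )
    geno = synth.simulate_snps(pedigree, n_snps=cfg.n_snps, seed=seeds[5])
    series, traits = synth.simulate_growth(
        layout, climate, truth, seed=seeds[6], drought_years=cfg.drought_years
    )
    # genotyped/phenotyped subsample: ~k alive trees per family per site
    rng2 = np.random.default_rng(seeds[7])
    picks = []
    for (site, fam), g in traits.groupby(["site", "family"]):
        k = min(cfg.subsample_per_family_site, len(g))
        picks.extend(rng2.choice(g["tree_id"].to_numpy(), size=k, replace=False))
    sample = sorted(picks)
    return {
        "layout": layout,
        "climate": climate,
        "pedigree": pedigree,
        "elevation": elevation,
        "truth": truth,
        "genotypes": geno,
        "series": series,
        "traits": traits,
        "sample": sample,
    }


def _design_ids(df):
    df = df.copy()
    df["block_id"] = df["site"].astype(str) + ":" + df["block"].astype(str)
    df["set_id"] = df["block_id"] + ":" + df["set"].astype(str)
    return df


def run_pipeline(cfg: RunConfig, write=True):
    """Execute every stage; returns the report dict (and writes tables)."""
    out = Path(cfg.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    report = {"seed": cfg.seed}

    stage = "synth"
    try:
        study = simulate_study(cfg)
        layout, truth = study["layout"], study["truth"]
        sample = study["sample"]
        log.info("synth: %d trees, %d sampled", len(layout), len(sample))
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "densitometry"
    try:
        detected = {}
        qc_scores = {}
        prof_seed = np.random.SeedSequence((cfg.seed, 101))
        child = prof_seed.spawn(len(sample))
        for k, tid in enumerate(sample):
            s = study["series"][tid]
            prof = synth.simulate_density_profile(
                s.widths, noise_sd=10.0, seed=child[k], tree_id=tid
            )
            und = densitometry.detect_ring_boundaries(prof)
            qc_scores[tid] = densitometry.ring_contrast_scores(prof, und)
            detected[tid] = densitometry.date_series(und, outermost_year=s.last_year)
        flags, discard_frac = densitometry.core_qc(detected, qc_scores, cfg.qc_threshold)
        kept = {t: s for t, s in detected.items() if flags[t]}
        report["densitometry"] = {
            "n_cores": len(detected),
            "discard_fraction": discard_frac,
        }
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "rings"
    try:
        idx = rings.drought_indices_table(
            kept, drought_years=cfg.drought_years, threshold=cfg.resilience_threshold
        )
        dbh_map = dict(zip(study["traits"]["tree_id"], study["traits"]["dbh30"]))
        ci = rings.competition_indices(layout, dbh_map, focal_ids=kept.keys())
        idx = idx.merge(ci.rename("competition"), left_on="tree_id", right_index=True, how="left")
        report["rings"] = {
            "n_trees": len(idx),
            "resilience_groups": idx["resilience_group"].value_counts().to_dict(),
        }
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "kinship"
    try:
        ped = study["pedigree"]
        geno_s = study["genotypes"].loc[[i for i in sample]]
        G = kinship.vanraden_g(geno_s)
        corrected, changes = kinship.assign_families(G, ped, cfg.unassigned_floor)
        A = kinship.a_matrix(
            corrected[corrected["id"].isin(set(sample) | set(ped.loc[ped["dam"].isna(), "id"]))]
        )
        report["kinship"] = {"n_reassigned": int(len(changes))}
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "lmm"
    try:
        data = study["traits"].merge(idx, on="tree_id", how="inner")
        data = _design_ids(data)
        data = data[data["tree_id"].isin(A.index)]
        h2 = {}
        bv_frames = {}
        for trait in INDEX_TRAITS:
            m = AnimalModel(
                trait=trait,
                relationship=A,
                fixed_effects=("site",),
                tol=cfg.reml_tol,
                max_iter=cfg.reml_max_iter,
                method=cfg.reml_method,
                denominator=cfg.h2_denominator,
            ).fit(data)
            h2[trait] = {"h2": m.heritability_, "se": m.heritability_se_,
                         "varcomp": m.varcomp_}
            bv_frames[trait] = m.breeding_values_
        bi = BivariateAnimalModel(
            traits=("resilience_2002", "decline"),
            relationship=A,
            fixed_effects=("site",),
            tol=cfg.reml_tol,
            max_iter=cfg.reml_max_iter,
            method=cfg.reml_method,
        ).fit(data)
        emm, contrasts = emmeans_tukey(data, "decline")
        report["lmm"] = {
            "heritability": {t: {"h2": v["h2"], "se": v["se"]} for t, v in h2.items()},
            "r_g_resilience2002_decline": bi.genetic_correlation_,
            "r_g_se": bi.genetic_correlation_se_,
            "emm_decline": emm.to_dict(orient="records"),
        }
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "sem"
    try:
        psem = PiecewiseSEM(spec=default_spec(), alpha=cfg.sem_alpha).fit(data)
        report["sem"] = {
            "fishers_c": psem.fishers_c_,
            "df": psem.df_,
            "p": psem.pvalue_,
            "n_added_links": len(psem.added_links_),
        }
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "adapt"
    try:
        dam_bv = pd.DataFrame(bv_frames)
        founders = study["pedigree"].loc[study["pedigree"]["dam"].isna(), "id"]
        fam_bv = dam_bv.loc[dam_bv.index.isin(founders)].copy()
        fam_bv["elevation"] = study["elevation"].reindex(fam_bv.index)
        regs = adapt_mod.elevation_regressions(
            fam_bv, ["resilience_2002", "resilience_2010", "decline"]
        )
        report["adapt"] = regs.to_dict(orient="records")
    except Exception as err:
        raise StageError(stage, err) from err

    if write:
        layout.to_csv(out / "layout.csv", index=False)
        study["climate"].monthly.to_csv(out / "climate_monthly.csv", index=False)
        study["climate"].annual.to_csv(out / "climate_annual.csv", index=False)
        study["pedigree"].to_csv(out / "pedigree.csv", index=False)
        study["genotypes"].round(0).to_csv(out / "genotypes.csv")
        ring_series_to_frame(kept).to_csv(out / "ring_widths.csv", index=False)
        write_rwl(kept, out / "rings.rwl")
        idx.to_csv(out / "drought_indices.csv", index=False)
        pd.DataFrame(bv_frames).to_csv(out / "breeding_values.csv")
        write_truth_json(truth, out / "truth.json")
        cfg.save(out / "config.yaml")
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def run_sem_only(data, spec=None, alpha=0.05):
    """Convenience wrapper used by the CLI ``sem`` subcommand."""
    return PiecewiseSEM(spec=spec or default_spec(), alpha=alpha).fit(data)
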