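"""End-to-end orchestration of the analysis.

Stages: cohort assembly -> position indices -> network structure with null
standardization -> modules and roles -> within-network sex tests ->
across-network comparative models.  Every stage writes a CSV; a JSON
summary and a log record all seeds and resolved settings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ectonet import comparative as comp
from ectonet import modroles, netcore, netstructure, positions, sexstats
from ectonet.synthdata import SimulationConfig, simulate_collection, write_collection

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("strength", "nested_rank", "dprime", "evcent")
# mapping from index to the comparative predictor naming convention
PREDICTOR_OF_INDEX = {
    "nested_rank": "dNR",
    "strength": "dSS",
    "evcent": "dEC",
    "dprime": "dDP",
}


@dataclass
class PipelineConfig:
    """Resolved settings for a full run.

    Defaults follow the study design the package implements: at least 20
    parasitized individuals per sex, 1000 null matrices, 10,000
    permutations, 95th-percentile role thresholds.
    """

    records: str | None = None
    tree: str | None = None
    simulate: SimulationConfig | None = None
    min_per_sex: int = 20
    n_null: int = 1000
    nperm: int = 10_000
    standardize_db_manova: bool = True
    response_scale: str = "zscore"  # or "raw"
    percentile: float = 95.0
    projection_method: str = "sum"
    seed: int = 0
    outdir: str = "ectonet_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "regions" in sim:
                sim["regions"] = tuple(sim["regions"])
            for key in ("abundance_mult_range", "composition_shift_range"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-item seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ectonet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"config": config.resolved(), "stages": {}}
    try:
        _run_stages(config, outdir, summary)
    finally:
        root.removeHandler(handler)
        handler.close()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _timed(summary: dict, stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            summary["stages"].setdefault(stage, {})
            logger.info("stage %s started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            summary["stages"].setdefault(stage, {})["elapsed_s"] = round(elapsed, 3)
            if exc_type is not None:
                summary["stages"][stage]["error"] = str(exc)
                logger.error("stage %s failed: %s", stage, exc)
            else:
                logger.info("stage %s finished in %.2fs", stage, elapsed)

    return _T()


def _run_stages(config: PipelineConfig, outdir: Path, summary: dict) -> None:
    # ---- stage: build -------------------------------------------------
    tree: dendropy.Tree | None = None
    with _timed(summary, "build"):
        if config.simulate is not None:
            bundles, tree, truth = simulate_collection(config.simulate)
            write_collection(bundles, tree, truth, outdir / "simulated")
            bundles = [
                b for b in bundles
                if min((b.sexes == "F").sum(), (b.sexes == "M").sum())
                >= config.min_per_sex
            ]
        elif config.records is not None:
            records, triples = netcore.read_records(config.records)
            bundles = netcore.build_networks(
                records, triples, min_per_sex=config.min_per_sex
            )
            if config.tree is not None:
                tree = comp.read_newick(config.tree)
        else:
            raise ValueError("config needs either a records path or a simulate block")
        if not bundles:
            raise ValueError("no network passed the per-sex filter")
        netcore.save_bundles(bundles, outdir / "networks")
        summary["stages"]["build"]["n_networks"] = len(bundles)

    # ---- stage: positions ---------------------------------------------
    with _timed(summary, "positions"):
        pos_tables = {}
        frames = []
        for b in bundles:
            pt = positions.position_table(b, projection_method=config.projection_method)
            pos_tables[b.id] = pt
            df = pt.table.copy()
            df.insert(0, "network", b.id)
            frames.append(df)
        pd.concat(frames).to_csv(outdir / "positions.csv", index=False)

    # ---- stage: structure ----------------------------------------------
    with _timed(summary, "structure"):
        seeds = _stage_seeds(config.seed, len(bundles))
        structures = {}
        rows = []
        for b, s in zip(bundles, seeds):
            res = netstructure.structure_with_nulls(b, n_null=config.n_null, seed=s)
            structures[b.id] = res
            rows.append(res.as_row())
        struct_df = pd.DataFrame(rows)
        struct_df.to_csv(outdir / "structure.csv", index=False)
        if len(struct_df) >= 3 and config.n_null > 0:
            r, p = sexstats.structure_correlation(
                struct_df["z_nodf"], struct_df["z_h2"]
            )
            summary["stages"]["structure"]["spearman_znodf_zh2"] = {"r": r, "p": p}

    # ---- stage: roles ---------------------------------------------------
    with _timed(summary, "roles"):
        seeds = _stage_seeds(config.seed + 1, len(bundles))
        role_rows, prop_rows, part_info = [], [], {}
        for b, s in zip(bundles, seeds):
            roles, part = modroles.host_roles(
                b, seed=s, percentile=config.percentile
            )
            df = roles.table.copy()
            df.insert(0, "network", b.id)
            role_rows.append(df)
            prop_rows.append(modroles.role_proportions_by_sex(roles, network_id=b.id))
            part_info[b.id] = {
                "Q": part.Q,
                "n_modules": part.n_modules,
                "seed": s,
                "host_module": part.host_module.tolist(),
                "parasite_module": part.parasite_module.tolist(),
            }
        pd.concat(role_rows).to_csv(outdir / "roles.csv", index=False)
        proportions = pd.concat(prop_rows)
        proportions.to_csv(outdir / "role_proportions.csv", index=False)
        (outdir / "modules.json").write_text(json.dumps(part_info, indent=2))

    # ---- stage: sexdiff -------------------------------------------------
    with _timed(summary, "sexdiff"):
        seeds = _stage_seeds(config.seed + 2, len(bundles))
        rows = []
        for b, s in zip(bundles, seeds):
            sex = b.sexes
            region, species, group = b.region, b.species, b.parasite_group
            meta = {"region": region, "species": species, "group": group}
            counts = b.matrix.counts.sum(axis=1)
            richness = (b.matrix.counts > 0).sum(axis=1)
            rows.append({**meta, **sexstats.nb_regression_counts(counts, sex).as_row()})
            rows.append({**meta, **sexstats.poisson_richness(richness, sex).as_row()})
            pos = pos_tables[b.id].table
            X = pos[list(INDEX_COLUMNS)].to_numpy()
            rows.append(
                {
                    **meta,
                    **sexstats.db_manova(
                        X,
                        sex,
                        nperm=config.nperm,
                        standardize=config.standardize_db_manova,
                        seed=s,
                    ).as_row(),
                }
            )
            for k, col in enumerate(INDEX_COLUMNS):
                rows.append(
                    {
                        **meta,
                        **sexstats.perm_anova_univariate(
                            pos[col].to_numpy(), sex, nperm=config.nperm,
                            seed=s + k + 1, index=col,
                        ).as_row(),
                    }
                )
        sex_df = pd.DataFrame(rows)
        sex_df.to_csv(outdir / "sex_tests.csv", index=False)
        summary["stages"]["sexdiff"]["n_tests"] = len(sex_df)

    # ---- stage: comparative --------------------------------------------
    if tree is None:
        logger.warning("no tree supplied: comparative stage skipped")
        summary["stages"]["comparative"] = {"skipped": "no tree"}
        return
    with _timed(summary, "comparative"):
        comp_df = comparative_table(
            bundles, pos_tables, structures, response_scale=config.response_scale
        )
        comp_df.to_csv(outdir / "comparative_table.csv", index=False)
        cov, tip_of = _expanded_covariance(tree, bundles)
        results = {}
        ranking_rows = []
        for group in sorted(comp_df["group"].unique()):
            sub = comp_df[comp_df["group"] == group]
            labels = [tip_of[(sp, rg)] for sp, rg in zip(sub["species"], sub["region"])]
            Csub = cov.subset(labels)
            for response in ("nodf", "h2"):
                y = sub[f"response_{response}"].to_numpy()
                preds = {p: sub[p].to_numpy() for p in comp.PREDICTORS}
                max_k = min(len(comp.PREDICTORS), len(y) - 3)
                if max_k < 1:
                    logger.warning(
                        "too few %s networks (%d) for PGLS on %s", group, len(y),
                        response,
                    )
                    continue
                best, ranking = comp.all_subsets_pgls(y, preds, Csub, max_k=max_k)
                for row in ranking:
                    ranking_rows.append({"group": group, "response": response, **row})
                results[f"{group}:{response}"] = {
                    "best_subset": ranking[0]["subset"],
                    "coefficients": dict(zip(best.names, best.beta.tolist())),
                    "t": dict(zip(best.names, best.t.tolist())),
                    "p_c": dict(zip(best.names, best.p.tolist())),
                    "r2": best.r2,
                    "f": best.f_stat,
                    "p_m": best.f_p,
                    "aic": best.aic,
                }
        pd.DataFrame(ranking_rows).to_csv(outdir / "pgls_ranking.csv", index=False)
        glmm = role_glmm_by_group(proportions, bundles)
        summary["stages"]["comparative"]["pgls"] = results
        summary["stages"]["comparative"]["beta_glmm"] = glmm
        (outdir / "comparative_models.json").write_text(
            json.dumps(
                {"pgls": results, "beta_glmm": glmm}, indent=2, default=float
            )
        )


def comparative_table(
    bundles,
    pos_tables,
    structures,
    response_scale: str = "zscore",
) -> pd.DataFrame:
    """One row per network: sex-difference predictors + structure responses."""
    rows = []
    for b in bundles:
        pos = pos_tables[b.id].table
        row = {
            "network": b.id,
            "species": b.species,
            "region": b.region,
            "group": b.parasite_group,
        }
        for col in INDEX_COLUMNS:
            mean_f = pos.loc[pos["sex"] == "F", col].mean()
            mean_m = pos.loc[pos["sex"] == "M", col].mean()
            row[PREDICTOR_OF_INDEX[col]] = comp.sex_difference_predictor(mean_f, mean_m)
        s = structures[b.id]
        if response_scale == "zscore":
            row["response_nodf"] = s.z_nodf
            row["response_h2"] = s.z_h2
        else:
            row["response_nodf"] = s.nodf_raw
            row["response_h2"] = s.h2_raw
        rows.append(row)
    return pd.DataFrame(rows)


def _expanded_covariance(tree: dendropy.Tree, bundles):
    """Brownian covariance with species sampled in several regions expanded
    into unit-length cherries of sister tips, unit branch lengths throughout."""
    species_regions: dict[str, list[str]] = {}
    for b in bundles:
        regions = species_regions.setdefault(b.species, [])
        if b.region not in regions:
            regions.append(b.region)
    tree = tree.clone(depth=1)
    tip_of: dict[tuple[str, str], str] = {}
    for sp, regions in species_regions.items():
        if len(regions) == 1:
            tip_of[(sp, regions[0])] = sp
        else:
            base = regions[0]
            tip_of[(sp, base)] = sp
            for extra in regions[1:]:
                label = f"{sp}|{extra}"
                comp.add_sister_tip(tree, tip_of[(sp, base)], label)
                tip_of[(sp, extra)] = label
    cov = comp.phylo_covariance(tree, unit_branches=True)
    return cov, tip_of


def role_glmm_by_group(proportions: pd.DataFrame, bundles) -> dict:
    """Beta mixed models of role proportions on sex.

    Fitted per parasite group: once per role (proportion ~ sex, species
    random intercept) and once pooled over roles with a role fixed effect.
    """
    species_of = {b.id: b.species for b in bundles}
    group_of = {b.id: b.parasite_group for b in bundles}
    df = proportions.copy()
    df["species"] = df["network"].map(species_of)
    df["pgroup"] = df["network"].map(group_of)
    out: dict = {}
    for group, gdf in df.groupby("pgroup"):
        out[group] = {}
        for role, rdf in gdf.groupby("role"):
            if rdf["species"].nunique() < 2 or rdf["sex"].nunique() < 2:
                continue
            X = np.column_stack(
                [np.ones(len(rdf)), (rdf["sex"] == "M").astype(float)]
            )
            try:
                fit = comp.beta_glmm_roles(
                    rdf["proportion"].to_numpy(), X, rdf["species"].to_numpy(),
                    names=["intercept", "sexM"],
                )
            except RuntimeError as exc:
                out[group][role] = {"error": str(exc)}
                continue
            out[group][role] = {
                "coef_sexM": float(fit["beta"][1]),
                "z": float(fit["z"][1]),
                "p": float(fit["p"][1]),
                "phi": fit["phi"],
                "sigma_b": fit["sigma_b"],
                "collapsed": fit["collapsed"],
            }
        # pooled variant with a role fixed effect
        pdf = gdf[gdf["sex"].isin(["F", "M"])]
        role_dummies = pd.get_dummies(pdf["role"], drop_first=True).astype(float)
        X = np.column_stack(
            [np.ones(len(pdf)), (pdf["sex"] == "M").astype(float), role_dummies]
        )
        try:
            fit = comp.beta_glmm_roles(
                pdf["proportion"].to_numpy(), X, pdf["species"].to_numpy(),
                names=["intercept", "sexM"] + list(role_dummies.columns),
            )
            out[group]["pooled_roles"] = {
                "coef_sexM": float(fit["beta"][1]),
                "z": float(fit["z"][1]),
                "p": float(fit["p"][1]),
                "sigma_b": fit["sigma_b"],
                "collapsed": fit["collapsed"],
            }
        except RuntimeError as exc:
            out[group]["pooled_roles"] = {"error": str(exc)}
    return out
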