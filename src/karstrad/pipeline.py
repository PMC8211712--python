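"""End-to-end orchestration of the adaptive-radiation workflow.

One configuration drives the full battery on a dataset (tree + habitat,
trait, coordinate and clade tables): genus-wide lineage-through-time and
gamma analysis, diversification model selection, stochastic mapping with
changes-through-time, trait preparation (PGLS size correction, pPCA),
disparity-through-time, node height tests, Ward morphotypes, multivariate
trait-model selection, SURFACE convergence and ancestral-area
reconstruction - then the same through-time battery per focal clade,
emitting a clade summary table.  Stages whose inputs are missing are
skipped with an explicit record; everything is deterministic given the
configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import os
import traceback
import warnings
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversification import DiversificationModel, compare_models, gamma_test, birth_death_model_family
from .disparity import dtt_test
from .geo import GeoBrownianModel
from .mk import MkModel, ancestral_state_frequencies, ctt_curve, ctt_null_test
from .surface import SurfaceModel
from .traitgeom import node_height_test, pgls_residuals, phylo_pca, ward_clusters
from .traitmodels import TraitEvolutionModel, compare_trait_models, shift_model_family
from .tree import TimeTree, validate_clades

__all__ = ["AnalysisConfig", "run_pipeline", "clade_screen", "prepare_traits"]


@dataclass
class AnalysisConfig:
    """Paths and per-stage parameters of one pipeline run."""

    tree: str
    habitats: Optional[str] = None
    traits: Optional[str] = None
    coordinates: Optional[str] = None
    clades: Optional[str] = None
    seed: int = 0
    n_gamma_nulls: int = 1000
    n_maps: int = 100
    n_ctt_sims: int = 200
    n_ctt_bins: int = 50
    n_dtt_sims: int = 1000
    min_clade_size: int = 25
    shift_age: Optional[float] = None  # None: taken from the diversification fit
    n_clusters: int = 9
    surface_max_shifts: int = 30
    geo_ages: List[float] = field(default_factory=lambda: [45.0, 15.0])
    n_geo_draws: int = 1000
    stages: Optional[List[str]] = None  # None = all
    body_length_column: str = "body_length_mm"
    log_body_length: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for attr in ("tree", "habitats", "traits", "coordinates", "clades"):
            p = getattr(cfg, attr)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{attr} file not found: {p}")
        return cfg


def clade_screen(
    tree: TimeTree, clades: Mapping[str, List[str]], min_size: int = 25
) -> Dict[str, List[str]]:
    """Clades large enough for through-time analysis (default >= 25 tips)."""
    return {k: list(v) for k, v in clades.items() if len(v) >= min_size}


def prepare_traits(
    tree: TimeTree,
    traits: pd.DataFrame,
    body_column: str = "body_length_mm",
    log_body: bool = False,
) -> pd.DataFrame:
    """Size correction: body length kept raw, all other traits replaced by
    phylogenetic GLS residuals of their regression on body length."""
    out = pd.DataFrame(index=traits.index)
    body = traits[body_column]
    if log_body:
        body = np.log(body)
    out[body_column] = body
    for col in traits.columns:
        if col == body_column:
            continue
        res = pgls_residuals(tree, traits[col], body)
        out[col] = res
    return out


def _read_table(path: str, col: Optional[str] = None):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if col is not None:
        return df[col].replace("?", np.nan)
    return df


def _clades_from_file(path: str) -> Dict[str, List[str]]:
    df = pd.read_csv(path, sep="\t")
    return {k: sorted(v["tip"]) for k, v in df.groupby("clade")}


def run_pipeline(config: AnalysisConfig, outdir: str) -> Dict[str, object]:
    """Run all configured stages; returns the report dict (also written to
    ``outdir`` as tables plus ``report.json`` and ``manifest.yaml``)."""
    os.makedirs(outdir, exist_ok=True)
    rng_seed = int(config.seed)
    report: Dict[str, object] = {"stages": {}, "skipped": {}, "errors": {}}
    want = lambda s: config.stages is None or s in config.stages

    tree = TimeTree.from_file(config.tree)
    habitats = _read_table(config.habitats, "habitat") if config.habitats else None
    traits_raw = _read_table(config.traits) if config.traits else None
    coords = _read_table(config.coordinates) if config.coordinates else None
    clades = _clades_from_file(config.clades) if config.clades else {}
    if clades:
        validate_clades(tree, clades)

    def stage(name, fn, *needs):
        if not want(name):
            report["skipped"][name] = "not requested"
            return None
        for label, obj in needs:
            if obj is None:
                report["skipped"][name] = f"missing input: {label}"
                return None
        try:
            out = fn()
            report["stages"][name] = out
            return out
        except Exception as exc:  # stage isolation
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            warnings.warn(f"stage {name} failed: {exc}\n{traceback.format_exc()}")
            return None

    # ---- diversification ---------------------------------------------
    def s_gamma():
        g = gamma_test(tree, n_null=config.n_gamma_nulls, seed=rng_seed)
        return {"gamma": g.gamma, "p": g.p_value, "n": g.n_tips}

    gamma_out = stage("gamma", s_gamma)

    def s_divmodels():
        fits = [
            DiversificationModel(tree, spec).fit()
            for spec in birth_death_model_family(pure_birth=True)
        ]
        tab = compare_models(fits)
        tab.to_csv(os.path.join(outdir, "diversification_models.tsv"), sep="\t", index=False)
        best = tab.iloc[0]
        return {
            "best_model": best["model"],
            "best_aic": float(best["AIC"]),
            "t_shift": None if pd.isna(best["t_shift"]) else float(best["t_shift"]),
            "table": tab.to_dict("records"),
        }

    div_out = stage("diversification_models", s_divmodels)
    shift_age = config.shift_age
    if shift_age is None and div_out and div_out.get("t_shift"):
        shift_age = float(div_out["t_shift"])
    if shift_age is None:
        shift_age = 0.33 * tree.crown_age

    # ---- habitats ----------------------------------------------------
    def s_ctt():
        fit = MkModel(tree, habitats, structure="SYM").fit()
        maps = fit.sample_maps(config.n_maps, seed=rng_seed + 1)
        obs = ctt_curve(tree, maps, n_bins=config.n_ctt_bins)
        res = ctt_null_test(
            tree, fit, obs, n_sims=config.n_ctt_sims, seed=rng_seed + 2
        )
        anc = ancestral_state_frequencies(tree, maps)
        anc.to_csv(os.path.join(outdir, "ancestral_habitats.tsv"), sep="\t")
        pd.DataFrame(
            {"bin_old_edge": res.bin_edges[:-1], "observed": res.observed,
             "edge_length": res.edge_length}
        ).to_csv(os.path.join(outdir, "ctt_curve.tsv"), sep="\t", index=False)
        return {
            "mean_rate": float(fit.rates.mean()),
            "loglik": fit.loglik,
            "p_interval": [res.envelope.p_lower, res.envelope.p_upper],
            "verdict": res.verdict,
        }

    ctt_out = stage("ctt", s_ctt, ("habitats", habitats))

    # ---- traits ------------------------------------------------------
    prepared = None
    if traits_raw is not None and want("trait_prep"):
        def s_prep():
            nonlocal prepared
            prepared = prepare_traits(
                tree, traits_raw.dropna(), config.body_length_column,
                config.log_body_length,
            )
            prepared.to_csv(os.path.join(outdir, "traits_prepared.tsv"), sep="\t")
            return {"n_species": int(prepared.shape[0]), "n_traits": int(prepared.shape[1])}

        stage("trait_prep", s_prep)

    def s_dtt():
        res = dtt_test(tree, prepared, n_sims=config.n_dtt_sims, seed=rng_seed + 3)
        pd.DataFrame({"rel_time": res.times, "observed": res.observed}).to_csv(
            os.path.join(outdir, "dtt_curve.tsv"), sep="\t", index=False
        )
        return {
            "mdi": res.mdi,
            "mdi_p_two_sided": res.mdi_p_two_sided,
            "p_interval": [res.envelope.p_lower, res.envelope.p_upper],
        }

    stage("dtt", s_dtt, ("prepared traits", prepared))

    def s_nht():
        rows = {}
        for col in prepared.columns:
            r = node_height_test(tree, prepared[col])
            rows[col] = {"slope": r.slope, "p": r.p_value}
        pd.DataFrame(rows).T.to_csv(os.path.join(outdir, "node_height_tests.tsv"), sep="\t")
        n_sig = sum(1 for v in rows.values() if v["p"] < 0.05 and v["slope"] > 0)
        return {"n_significant_positive": n_sig, "n_traits": len(rows)}

    stage("node_height", s_nht, ("prepared traits", prepared))

    ppca_scores = None

    def s_ppca():
        nonlocal ppca_scores
        res = phylo_pca(tree, prepared)
        ppca_scores = res.scores.iloc[:, :2]
        res.scores.to_csv(os.path.join(outdir, "ppca_scores.tsv"), sep="\t")
        return {"cumvar2": float(res.cumulative_variance[min(1, len(res.cumulative_variance) - 1)])}

    stage("ppca", s_ppca, ("prepared traits", prepared))

    def s_clusters():
        labels, _ = ward_clusters(prepared, k=config.n_clusters)
        labels.to_csv(os.path.join(outdir, "morphotype_clusters.tsv"), sep="\t")
        return {"k": int(labels.nunique())}

    cluster_out = stage("morphotypes", s_clusters, ("prepared traits", prepared))

    def s_traitmodels():
        fits = [
            TraitEvolutionModel(tree, ppca_scores, spec).fit()
            for spec in shift_model_family(shift_age)
        ]
        tab = compare_trait_models(fits)
        tab.to_csv(os.path.join(outdir, "trait_models.tsv"), sep="\t", index=False)
        return {"best_model": tab.iloc[0]["model"], "shift_age": shift_age,
                "table": tab.to_dict("records")}

    stage("trait_models", s_traitmodels, ("pPCA scores", ppca_scores))

    def s_surface():
        res = SurfaceModel(tree, ppca_scores).fit(max_shifts=config.surface_max_shifts)
        rows = [{"branch": b, "regime": r} for b, r in sorted(res.fit.painting.items())]
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "surface_painting.tsv"), sep="\t", index=False)
        res.fit.optima.to_csv(os.path.join(outdir, "surface_optima.tsv"), sep="\t")
        return {
            "n_shifts": res.n_shifts,
            "n_peaks": res.n_regimes,
            "n_convergent": res.n_convergent,
            "n_unique": res.n_unique,
        }

    stage("surface", s_surface, ("pPCA scores", ppca_scores))

    # ---- geography ---------------------------------------------------
    def s_geo():
        model = GeoBrownianModel(tree, coords)
        targets = [tuple(model.tips)]
        targets += [("slice", tuple(model.tips), a) for a in config.geo_ages
                    if a < tree.crown_age]
        recs = model.reconstruct(targets, n_draws=config.n_geo_draws, seed=rng_seed + 4)
        out = []
        for t, r in zip(targets, recs):
            lon, lat = r.centroid_lonlat
            name = "root" if not (isinstance(t, tuple) and t and t[0] == "slice") else f"age_{t[2]}"
            out.append({"target": name, "lon": lon, "lat": lat})
        pd.DataFrame(out).to_csv(os.path.join(outdir, "geo_centroids.tsv"), sep="\t", index=False)
        return {"centroids": out}

    stage("geography", s_geo, ("coordinates", coords))

    # ---- per-clade battery -------------------------------------------
    def s_clades():
        eligible = clade_screen(tree, clades, config.min_clade_size)
        rows = []
        for name, tips in eligible.items():
            sub = tree.extract_clade(tips)
            row: Dict[str, object] = {"clade": name, "n_species": sub.n_tips}
            g = gamma_test(sub, n_null=config.n_gamma_nulls, seed=rng_seed + 10)
            row["gamma"], row["gamma_p"] = g.gamma, g.p_value
            if habitats is not None:
                sub_hab = habitats[habitats.index.isin(tips)]
                row["n_habitats"] = int(sub_hab.dropna().nunique())
                try:
                    fit = MkModel(sub, sub_hab, structure="ER").fit()
                    maps = fit.sample_maps(max(20, config.n_maps // 5), seed=rng_seed + 11)
                    obs = ctt_curve(sub, maps, n_bins=max(10, config.n_ctt_bins // 5))
                    res = ctt_null_test(sub, fit, obs,
                                        n_sims=max(50, config.n_ctt_sims // 2),
                                        seed=rng_seed + 12)
                    row["ctt"] = res.verdict
                except Exception as exc:
                    row["ctt"] = "n.a."
            if prepared is not None:
                have = prepared.index.intersection(tips)
                if len(have) >= max(4, len(tips) // 3):
                    try:
                        d = dtt_test(sub, prepared.loc[have],
                                     n_sims=max(100, config.n_dtt_sims // 5),
                                     seed=rng_seed + 13)
                        row["mdi"] = d.mdi
                        row["dtt_p_interval"] = (
                            f"{d.envelope.p_lower:.4f}-{d.envelope.p_upper:.4f}"
                        )
                    except Exception:
                        row["mdi"], row["dtt_p_interval"] = np.nan, "n.a."
                else:
                    row["mdi"], row["dtt_p_interval"] = np.nan, "n.a."
            if cluster_out is not None and prepared is not None:
                labels, _ = ward_clusters(prepared, k=config.n_clusters)
                row["n_morphotypes"] = int(labels[labels.index.isin(tips)].nunique())
            rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(os.path.join(outdir, "clade_report.tsv"), sep="\t", index=False)
        return df.to_dict("records")

    stage("clades", s_clades, ("clades", clades if clades else None))

    manifest = {
        "version": __version__,
        "seed": rng_seed,
        "config": {k: v for k, v in vars(config).items()},
        "n_tips": tree.n_tips,
        "crown_age": tree.crown_age,
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
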