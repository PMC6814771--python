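"""End-to-end orchestration: simulate -> QC/karyotype -> curate -> prepare
-> tune/score PGS -> expressivity statistics -> report.

Each stage is independently callable; ``run_pipeline`` chains them and
emits analogues of the study's main exhibits: the carrier effect-size table
(Table-1-like), the within-carrier polygenic effect table with power and
Bonferroni columns (Table-2-like), percentile-bin means with equivalence
percentiles (Fig-1-like), tertile summaries (Fig-2-like), the direction
signs test, coefficient-equality tests and the extreme-bin logistic models,
plus a manifest (config snapshot, seed, per-stage row counts, output
digests) that makes a run reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, prep, stats, synth
from .aneuploidy import CallerThresholds, call_cohort
from .pgs import WeightSet, percentile_bins, score, standardize_scores, tertiles, tune_rho

log = logging.getLogger(__name__)

COVARIATES = ["age", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "batch"]


@dataclass
class PipelineConfig:
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    rho_grid: list[float] = field(default_factory=lambda: [1.0, 0.3, 0.1, 0.03, 0.01, 0.003, 0.001])
    rho_star: float = 0.1
    validation_n: int = 10000
    excluded_batches: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        cfg = cls()
        if "generator" in raw:
            gen_kwargs = raw["generator"]
            cfg.generator = synth.GeneratorConfig(**gen_kwargs)
        if "thresholds" in raw:
            cfg.thresholds = CallerThresholds(**raw["thresholds"])
        for key in ("rho_grid", "rho_star", "validation_n", "excluded_batches"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def to_dict(self) -> dict:
        return {
            "generator": dataclasses.asdict(self.generator),
            "thresholds": dataclasses.asdict(self.thresholds),
            "rho_grid": list(self.rho_grid),
            "rho_star": self.rho_star,
            "validation_n": self.validation_n,
            "excluded_batches": list(self.excluded_batches),
        }


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration: Table-1 carrier counts over a reduced
    variant-negative cohort and SNP panel, for fast end-to-end runs."""
    gen = synth.GeneratorConfig(n_variant_negative=6000, n_snps=300,
                                n_related_pairs=40, n_third_degree_pairs=15, seed=seed)
    return PipelineConfig(generator=gen, validation_n=1500)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig):
    cohort = synth.generate_cohort(config.generator)
    signals = synth.generate_array_signals(cohort)
    variants = synth.generate_variant_table(cohort)
    fam_rng = np.random.default_rng(config.generator.seed + 4)
    family = [WeightSet(rho, df) for rho, df in
              synth.make_weight_family(cohort.true_weights, config.rho_grid,
                                       config.rho_star, fam_rng).items()]
    return cohort, signals, variants, family


def stage_karyotype(signals: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    return call_cohort(signals, config.thresholds, config.excluded_batches)


def stage_curate(variants: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    return curation.assign_rgds(variants, calls)


def stage_prep(cohort: synth.Cohort, assignments: pd.DataFrame):
    """Aggregation, exclusions, pruning and per-trait standardization.

    Returns (adjusted long table, included sample frame, exclusion log,
    per-trait reference-id sets)."""
    agg = prep.aggregate_phenotypes(cohort.phenotypes)
    samples = cohort.samples.merge(agg, on="sample_id", how="left")
    samples, exclusion_log = prep.apply_exclusions(samples)

    trait_cols = [t for t in cohort.config.trait_specs if t in samples.columns]
    missing = samples.set_index("sample_id")[trait_cols].isna().sum(axis=1).to_dict()
    kept = prep.prune_relatives(cohort.kinship, samples["sample_id"], missing)
    samples = samples[samples["sample_id"].isin(kept)].reset_index(drop=True)

    assigned_by_trait = {
        trait: set(assignments.loc[(assignments["trait"] == trait) & ~assignments["conflict"],
                                   "sample_id"])
        for trait in synth.DEFAULT_TRAIT_SPECS
    }
    any_assigned = set(assignments["sample_id"])

    adjusted = {}
    refs = {}
    for trait in cohort.config.trait_specs:
        ref_ids = set(samples["sample_id"]) - any_assigned
        refs[trait] = ref_ids
        adjusted[trait] = prep.preadjust_standardize(samples, trait, COVARIATES, ref_ids)
    adj = pd.concat(adjusted.values(), ignore_index=True)
    return adj, samples, exclusion_log, refs, assigned_by_trait


def stage_pgs(cohort, family, adjusted, samples, refs, config: PipelineConfig):
    """Validation split, rho tuning per trait, scoring, binning, tertiles."""
    rng = np.random.default_rng(config.generator.seed + 5)
    neg_ids = sorted(set.union(*[set(r) for r in refs.values()]) if refs else set())
    n_val = min(config.validation_n, max(0, len(neg_ids) - 200))
    val_ids = set(rng.choice(neg_ids, size=n_val, replace=False))

    dosages = cohort.dosages.loc[cohort.dosages.index.isin(samples["sample_id"])]
    results = {}
    for trait in cohort.config.trait_specs:
        adj_t = adjusted[adjusted["trait"] == trait].set_index("sample_id")["z_value"]
        val_idx = dosages.index.intersection(pd.Index(sorted(val_ids))).intersection(adj_t.index)
        best, table = tune_rho(family, dosages.loc[val_idx], adj_t)
        raw = score(dosages, best)
        test_ref = sorted(set(refs[trait]) - val_ids)
        std = standardize_scores(raw, test_ref)
        val_score = raw.loc[val_idx]
        val_r2 = float(np.corrcoef(val_score, adj_t.loc[val_idx])[0, 1] ** 2)
        bins = percentile_bins(std, test_ref)
        results[trait] = {
            "selected_rho": best.rho, "r2_table": table, "validation_r2": val_r2,
            "scores": std, "bins": bins, "test_ref": test_ref,
        }
    return results, sorted(val_ids)


def stage_analyze(cohort, adjusted, pgs_results, assigned_by_trait, samples,
                  config: PipelineConfig):
    """All estimation/testing downstream of scoring; returns the bundle."""
    bundle: dict = {"traits": {}, "rgds": {}}
    rgd_order = [(label, trait) for label, trait, *_ in config.generator.rgd_specs]
    n_per_trait = {t: sum(1 for _, tt in rgd_order if tt == t) for t in set(t for _, t in rgd_order)}

    pgs_betas = {}
    for label, trait in rgd_order:
        pr = pgs_results[trait]
        adj_t = adjusted[adjusted["trait"] == trait].set_index("sample_id")["z_value"]
        carriers = sorted(assigned_by_trait[trait] & set(adj_t.index)
                          & set(samples.loc[samples["rgd_label"] == label, "sample_id"]))
        analysis_ids = pd.Index(pr["test_ref"]).append(pd.Index(carriers))
        z = adj_t.loc[analysis_ids].to_numpy()
        flag = np.concatenate([np.zeros(len(pr["test_ref"])), np.ones(len(carriers))])
        pgs_vals = pr["scores"].loc[analysis_ids].to_numpy()
        entry: dict = {"trait": trait, "n": len(carriers)}
        if len(carriers) >= 3:
            eff = stats.carrier_effect(z, flag)
            adj_eff = stats.carrier_effect_pgs_adjusted(z, flag, pgs_vals)
            pe = stats.pgs_effect_in_carriers(z, pgs_vals, flag.astype(bool))
            ref_mask = flag == 0
            ref_fit = stats.pgs_effect_in_carriers(z, pgs_vals, ref_mask)
            inter = stats.z_diff(ref_fit.beta, ref_fit.se, pe.beta, pe.se)
            bins_carrier = pr["bins"].loc[analysis_ids].to_numpy()
            extreme_k = 100 if eff.beta >= 0 else 1
            bc = stats.bin_comparison(z, bins_carrier, flag.astype(bool), extreme_k)
            tert = tertiles(pr["scores"], carriers)
            tsum = stats.tertile_summary(adj_t.loc[carriers].to_numpy(),
                                         tert.loc[carriers].to_numpy())
            power = stats.power_correlation(pgs_results[trait]["validation_r2"], len(carriers))
            pgs_betas[label] = pe.beta
            entry.update({
                "carrier_effect": dataclasses.asdict(eff),
                "carrier_effect_pgs_adjusted": dataclasses.asdict(adj_eff),
                "pgs_effect": dataclasses.asdict(pe),
                "pgs_effect_p_corrected": stats.bonferroni(pe.p, n_per_trait[trait]),
                "power": dataclasses.asdict(power),
                "z_diff": dataclasses.asdict(inter),
                "extreme_bin_contrast": dataclasses.asdict(bc),
                "tertile_summary": tsum.to_dict("records"),
            })
        bundle["rgds"][label] = entry

    for trait, pr in pgs_results.items():
        adj_t = adjusted[adjusted["trait"] == trait].set_index("sample_id")["z_value"]
        ref_ids = pd.Index(pr["test_ref"]).intersection(adj_t.index)
        zref = adj_t.loc[ref_ids].to_numpy()
        sref = pr["scores"].loc[ref_ids].to_numpy()
        ref_fit = stats.pgs_effect_in_carriers(zref, sref, np.ones(len(ref_ids), dtype=bool))
        bins = pr["bins"].loc[ref_ids].to_numpy()
        bin_means = pd.DataFrame({"bin": np.arange(1, 101)}).assign(
            mean_z=[zref[bins == b].mean() if (bins == b).any() else np.nan
                    for b in range(1, 101)])
        bundle["traits"][trait] = {
            "selected_rho": pr["selected_rho"],
            "validation_r2": pr["validation_r2"],
            "testing_r2": ref_fit.r2,
            "reference_pgs_effect": dataclasses.asdict(ref_fit),
            "bin_means": bin_means.to_dict("records"),
            "n_reference": int(len(ref_ids)),
        }

    n_pos = sum(1 for b in pgs_betas.values() if b > 0)
    bundle["signs_test"] = {
        "n_positive": n_pos, "n_total": len(pgs_betas),
        "p": stats.signs_test(n_pos, len(pgs_betas)) if pgs_betas else None,
    }

    # extreme-bin logistic models on the LDL-C testing reference population
    pr = pgs_results.get("LDL-C")
    if pr is not None:
        ref_ids = pd.Index(pr["test_ref"])
        s = samples.set_index("sample_id").loc[ref_ids]
        top = (pr["bins"].loc[ref_ids] == 100).to_numpy().astype(float)
        covar = np.column_stack([s["age"].to_numpy(), (s["sex"] == "F").to_numpy(dtype=float)])
        for name in ("statin", "cad"):
            try:
                fit = stats.extreme_bin_logistic(s[name].to_numpy(dtype=float), top, covar)
                bundle[f"{name}_top_bin_or"] = dataclasses.asdict(fit)
            except ValueError as exc:
                bundle[f"{name}_top_bin_or"] = {"error": str(exc)}
    return bundle


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> tuple[dict, dict]:
    """Run every stage; write tables, results bundle and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.generator.seed

    log.info("stage simulate")
    cohort, signals, variants, family = stage_simulate(config)
    log.info("simulated %d samples, %d variants", len(cohort.samples), len(variants))

    log.info("stage karyotype")
    calls = stage_karyotype(signals, config)
    log.info("stage curate")
    assignments = stage_curate(variants, calls)
    log.info("assigned %d sample-label pairs", len(assignments))

    log.info("stage prep")
    adjusted, samples, exclusion_log, refs, assigned_by_trait = stage_prep(cohort, assignments)
    log.info("included %d samples after exclusions/pruning", len(samples))

    log.info("stage pgs")
    pgs_results, val_ids = stage_pgs(cohort, family, adjusted, samples, refs, config)

    log.info("stage analyze")
    bundle = stage_analyze(cohort, adjusted, pgs_results, assigned_by_trait, samples, config)

    tables = {
        "calls.tsv": calls,
        "assignments.tsv": assignments,
        "adjusted_traits.tsv": adjusted,
        "exclusions.tsv": exclusion_log,
        "table1_analogue.tsv": _table1(bundle),
        "table2_analogue.tsv": _table2(bundle),
        "fig1_bin_means.tsv": _fig1(bundle),
        "fig2_tertiles.tsv": _fig2(bundle),
    }
    for name, df in tables.items():
        synth.write_tsv(df, out / name, seed=seed)
    with open(out / "results.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=1)

    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "counts": {
            "samples_generated": int(len(cohort.samples)),
            "samples_included": int(len(samples)),
            "variants": int(len(variants)),
            "assignments": int(len(assignments)),
            "validation": len(val_ids),
        },
        "digests": {name: _digest(out / name) for name in tables},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return bundle, manifest


def _table1(bundle) -> pd.DataFrame:
    rows = []
    for label, e in bundle["rgds"].items():
        ce = e.get("carrier_effect")
        if ce:
            rows.append((e["trait"], label, ce["beta"], ce["ci_low"], ce["ci_high"],
                         ce["p"], e["n"]))
    return pd.DataFrame(rows, columns=["trait", "rgd", "beta", "ci_low", "ci_high", "p", "n"])


def _table2(bundle) -> pd.DataFrame:
    rows = []
    for trait, t in bundle["traits"].items():
        r = t["reference_pgs_effect"]
        rows.append((trait, "variant-negative", r["beta"], r["ci_low"], r["ci_high"],
                     r["p"], np.nan, t["testing_r2"], np.nan, r["n"]))
    for label, e in bundle["rgds"].items():
        pe = e.get("pgs_effect")
        if pe:
            rows.append((e["trait"], label, pe["beta"], pe["ci_low"], pe["ci_high"], pe["p"],
                         e["pgs_effect_p_corrected"], pe["r2"], e["power"]["power"], e["n"]))
    return pd.DataFrame(rows, columns=["trait", "rgd", "beta", "ci_low", "ci_high",
                                       "p", "p_corrected", "r2", "power", "n"])


def _fig1(bundle) -> pd.DataFrame:
    rows = []
    for trait, t in bundle["traits"].items():
        for rec in t["bin_means"]:
            rows.append((trait, rec["bin"], rec["mean_z"]))
    return pd.DataFrame(rows, columns=["trait", "bin", "mean_z"])


def _fig2(bundle) -> pd.DataFrame:
    rows = []
    for label, e in bundle["rgds"].items():
        for rec in e.get("tertile_summary", []):
            rows.append((e["trait"], label, rec["tertile"], rec["mean"], rec["sem"], rec["n"]))
    return pd.DataFrame(rows, columns=["trait", "rgd", "tertile", "mean_z", "sem", "n"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report(bundle: dict, out_dir) -> list[Path]:
    """Percentile-bin scatter with carrier reference lines, and tertile bar
    charts with SEM error bars; one figure per trait."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not bundle or "traits" not in bundle or not bundle["traits"]:
        raise ValueError("empty results bundle: run the pipeline first")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for trait, t in bundle["traits"].items():
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        bins = [r["bin"] for r in t["bin_means"]]
        means = [r["mean_z"] for r in t["bin_means"]]
        ax1.scatter(bins, means, s=10, c=bins, cmap="Blues")
        for label, e in bundle["rgds"].items():
            if e["trait"] == trait and "carrier_effect" in e:
                beta = e["carrier_effect"]["beta"]
                ax1.axhline(beta, ls="--", lw=0.8, color="red" if beta > 0 else "blue")
                ax1.annotate(label, (2, beta), fontsize=7)
        ax1.set_xlabel("PGS percentile bin")
        ax1.set_ylabel(f"mean standardized {trait}")

        x0 = 0
        for label, e in bundle["rgds"].items():
            if e["trait"] == trait and e.get("tertile_summary"):
                ts = e["tertile_summary"]
                xs = [x0 + i for i in range(len(ts))]
                ax2.bar(xs, [r["mean"] for r in ts],
                        yerr=[r["sem"] for r in ts],
                        color=["gold", "orange", "red"][: len(ts)], capsize=2)
                ax2.annotate(label, (x0, 0), rotation=90, fontsize=6)
                x0 += len(ts) + 1
        ax2.set_ylabel(f"mean standardized {trait} by PGS tertile")
        fig.tight_layout()
        path = out / f"report_{trait.replace('-', '').lower()}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
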