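"""Relatedness pruning, phenotype aggregation/exclusions, and sex-stratified
covariate pre-adjustment to standardized traits."""

from _common import SEED, config, outdir

from polyexpress import pipeline, synth


def main():
    cfg = config()
    cohort, signals, variants, _ = pipeline.stage_simulate(cfg)
    calls = pipeline.stage_karyotype(signals, cfg)
    assignments = pipeline.stage_curate(variants, calls)
    adjusted, samples, excl, refs, _ = pipeline.stage_prep(cohort, assignments)
    out = outdir("04_prepared")
    synth.write_tsv(adjusted, out / "adjusted_traits.tsv", SEED)
    synth.write_tsv(excl, out / "exclusions.tsv", SEED)
    for trait, grp in adjusted.groupby("trait"):
        ref = grp[grp["sample_id"].isin(refs[trait])]
        print(f"{trait}: n={len(grp)}, reference mean={ref['z_value'].mean():+.2e}, "
              f"var={ref['z_value'].var(ddof=0):.4f}")
    print(f"included {len(samples)} of {len(cohort.samples)} samples "
          f"({len(excl)} excluded, {len(cohort.samples) - len(excl) - len(samples)} pruned) -> {out}")


if __name__ == "__main__":
    main()
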