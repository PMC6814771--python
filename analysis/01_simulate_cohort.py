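"""Simulate the study cohort: variant-negative population plus the eleven
carrier groups, SNP-array signals, variant table and kinship pairs."""

from _common import SEED, config, outdir

from polyexpress import pipeline, synth


def main():
    cfg = config()
    cohort, signals, variants, family = pipeline.stage_simulate(cfg)
    out = outdir("01_cohort")
    synth.write_tsv(cohort.samples.drop(columns=[c for c in cohort.samples
                                                 if c.startswith("true_z_")]),
                    out / "samples.tsv", SEED)
    synth.write_tsv(cohort.phenotypes, out / "phenotypes.tsv", SEED)
    synth.write_tsv(cohort.kinship, out / "kinship.tsv", SEED)
    synth.write_tsv(signals, out / "signals.tsv", SEED)
    synth.write_tsv(variants, out / "variants.tsv", SEED)
    n_car = (cohort.samples["rgd_label"] != "").sum()
    print(f"simulated {len(cohort.samples)} samples ({n_car} carriers across "
          f"{cohort.samples['rgd_label'].nunique() - 1} disorders), "
          f"{len(variants)} variants, {len(cohort.kinship)} kinship pairs -> {out}")


if __name__ == "__main__":
    main()
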