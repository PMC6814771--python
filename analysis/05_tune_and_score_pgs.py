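"""Tune the polygenic-score weighting parameter rho on the validation
split, score and standardize the testing cohort, and report the variance
explained per trait."""

from _common import SEED, config, outdir

from polyexpress import pipeline, synth


def main():
    cfg = config()
    cohort, signals, variants, family = pipeline.stage_simulate(cfg)
    calls = pipeline.stage_karyotype(signals, cfg)
    assignments = pipeline.stage_curate(variants, calls)
    adjusted, samples, _, refs, _ = pipeline.stage_prep(cohort, assignments)
    pgs_results, val_ids = pipeline.stage_pgs(cohort, family, adjusted, samples, refs, cfg)
    out = outdir("05_pgs")
    for trait, pr in pgs_results.items():
        synth.write_tsv(pr["r2_table"], out / f"r2_table_{trait.replace('-', '')}.tsv", SEED)
        print(f"{trait}: selected rho={pr['selected_rho']} "
              f"(validation R^2={pr['validation_r2']:.4f}) over grid of "
              f"{len(pr['r2_table'])} candidates; validation n={len(val_ids)}")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
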