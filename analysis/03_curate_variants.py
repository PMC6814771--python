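"""Apply the gene-level curation rules and karyotype calls to assign each
sample its disorder label; decoy variants must all be rejected."""

from _common import SEED, config, outdir

from polyexpress import pipeline, synth


def main():
    cfg = config()
    cohort, signals, variants, _ = pipeline.stage_simulate(cfg)
    calls = pipeline.stage_karyotype(signals, cfg)
    assignments = pipeline.stage_curate(variants, calls)
    out = outdir("03_assignments")
    synth.write_tsv(assignments, out / "assignments.tsv", SEED)

    planted = cohort.samples.set_index("sample_id")["rgd_label"]
    decoys = {s for s in variants["sample_id"] if planted[s] == ""}
    rejected = len(decoys - set(assignments["sample_id"]))
    print(f"{len(assignments)} assignments across "
          f"{assignments['rgd_label'].nunique()} disorders; "
          f"decoys rejected: {rejected}/{len(decoys)} -> {out}")


if __name__ == "__main__":
    main()
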