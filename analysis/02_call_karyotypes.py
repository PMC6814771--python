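"""Call sex-chromosome complements from the array signals and check the
planted complements are recovered."""

import pandas as pd

from _common import SEED, config, outdir

from polyexpress import pipeline, synth


def main():
    cfg = config()
    cohort, signals, *_ = pipeline.stage_simulate(cfg)
    calls = pipeline.stage_karyotype(signals, cfg)
    out = outdir("02_karyotypes")
    synth.write_tsv(calls, out / "calls.tsv", SEED)

    truth = signals.set_index("sample_id")["true_karyotype"]
    called = calls.set_index("sample_id")["karyotype"]
    tab = pd.crosstab(truth, called)
    tab.to_csv(out / "confusion.tsv", sep="\t")
    n45 = called.isin(["45,X", "45,X/46,XX"]).sum()
    n_complete = (called == "45,X").sum()
    print(f"called {len(calls)} samples; 45,X group: {n45} "
          f"({n_complete} complete, {n45 - n_complete} mosaic); "
          f"ambiguous: {(called == 'ambiguous').sum()} -> {out}")


if __name__ == "__main__":
    main()
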