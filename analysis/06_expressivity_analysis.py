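"""Full chain to the expressivity statistics: carrier effect sizes,
within-carrier polygenic effects with power and Bonferroni columns,
percentile-bin equivalences, tertile summaries, the direction signs test
and the extreme-bin logistic models."""

import json

from _common import config, outdir

from polyexpress import pipeline


def main():
    cfg = config()
    out = outdir("06_expressivity")
    bundle, manifest = pipeline.run_pipeline(cfg, out)
    st = bundle["signs_test"]
    print(f"signs test: {st['n_positive']}/{st['n_total']} polygenic effects "
          f"positive, two-tailed p={st['p']:.3e}")
    for label, e in bundle["rgds"].items():
        ce, pe = e["carrier_effect"], e["pgs_effect"]
        print(f"{label:20s} ({e['trait']:6s}) carrier beta={ce['beta']:+.2f} "
              f"[{ce['ci_low']:+.2f},{ce['ci_high']:+.2f}] n={e['n']:3d} | "
              f"PGS beta={pe['beta']:+.2f} p={pe['p']:.2e} "
              f"p_corr={e['pgs_effect_p_corrected']:.2e} power={e['power']['power']:.2f}")
    if "statin_top_bin_or" in bundle and "beta" in bundle["statin_top_bin_or"]:
        o = bundle["statin_top_bin_or"]
        print(f"statin odds in top LDL-C PGS bin: OR={o['beta']:.2f} "
              f"[{o['ci_low']:.2f},{o['ci_high']:.2f}]")
    print(f"tables and results.json -> {out}")


if __name__ == "__main__":
    main()
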