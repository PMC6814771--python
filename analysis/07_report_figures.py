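"""Render the percentile-bin and tertile figures from the expressivity
results bundle (run 06_expressivity_analysis.py first, or this script will
compute the bundle itself)."""

import json

from _common import config, outdir

from polyexpress import pipeline


def main():
    src = outdir("06_expressivity") / "results.json"
    if src.exists():
        bundle = json.loads(src.read_text())
    else:
        bundle, _ = pipeline.run_pipeline(config(), outdir("06_expressivity"))
    paths = pipeline.report(bundle, outdir("07_figures"))
    print("wrote " + ", ".join(str(p) for p in paths))


if __name__ == "__main__":
    main()
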