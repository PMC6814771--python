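"""Shared configuration for the numbered analysis scripts.

One desk-scale study configuration (seed 1) drives every script; each
script re-derives the stages it needs (stages are deterministic functions
of the config) and writes its tables under results/.
"""

from pathlib import Path

from polyexpress.pipeline import demo_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def config():
    return demo_config(seed=SEED)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
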