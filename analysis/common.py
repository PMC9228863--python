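"""Shared run configuration for the numbered analysis drivers."""

import argparse

from fadsmets.cohort import default_config
from fadsmets.pipeline import PipelineConfig


def run_config(description: str) -> PipelineConfig:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=str, default="results/run")
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()
    cfg = PipelineConfig(outdir=args.out, seed=args.seed,
                         generator=default_config(seed=args.seed),
                         n_perm=args.n_perm)
    return cfg
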