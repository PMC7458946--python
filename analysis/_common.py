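"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from cifrisk.pipeline import PipelineConfig


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=17)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    return parser.parse_args()


def make_config(args: argparse.Namespace) -> PipelineConfig:
    return PipelineConfig(out_dir=args.out, seed=args.seed,
                          log_level="WARNING")
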