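"""Shared argument handling for the numbered analysis scripts.

Every script operates on one run directory; later scripts read the
artifacts earlier ones wrote, so they can be run one by one or all in
sequence with the same --outdir and --seed.
"""

import argparse
import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sdmfuse.config import RunConfig  # noqa: E402


def run_config(description: str) -> RunConfig:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--outdir", default="results/analysis")
    ap.add_argument("--seed", type=int, default=20200416)
    ap.add_argument("--config", default=None,
                    help="optional RunConfig YAML; --seed/--outdir override it")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    if args.config:
        cfg = RunConfig.from_yaml(args.config)
        cfg = RunConfig(**{**cfg.__dict__, "seed": args.seed, "outdir": args.outdir})
    else:
        cfg = RunConfig(outdir=args.outdir, seed=args.seed)
    return cfg
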