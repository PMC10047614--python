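#!/usr/bin/env python
"""Config-driven end-to-end run of the whole pipeline.

    python analysis/run_all.py --config my_run.yaml
    python analysis/run_all.py --mode spatial --seed 7 --outdir results/run

Exit codes: 0 success, 2 configuration error, 3 data validation error,
4 model non-convergence (artifacts written up to the failing stage).
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from fidescape.filtering import SchemaError
from fidescape.glmm import ConvergenceError
from fidescape.pipeline import PipelineConfig, run_pipeline
from fidescape.simulate import ConfigurationError


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", type=Path, help="YAML pipeline configuration")
    ap.add_argument("--mode", choices=["tabular", "spatial", "real_csv"])
    ap.add_argument("--seed", type=int)
    ap.add_argument("--outdir", type=str)
    args = ap.parse_args()

    try:
        cfg = PipelineConfig.from_yaml(args.config) if args.config \
            else PipelineConfig()
        if args.mode:
            cfg.mode = args.mode
        if args.seed is not None:
            cfg.seed = args.seed
        if args.outdir:
            cfg.outdir = args.outdir
        res = run_pipeline(cfg)
    except ConfigurationError as exc:
        print(f"configuration error: {exc}", file=sys.stderr)
        return 2
    except SchemaError as exc:
        print(f"data validation error: {exc}", file=sys.stderr)
        return 3
    except ConvergenceError as exc:
        print(f"model non-convergence: {exc}", file=sys.stderr)
        return 4

    for line in res["manifest"]["log"]:
        print(line)
    print(f"artifacts in {cfg.outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
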