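"""Shared setup for the analysis drivers.

Each numbered script regenerates the same seeded synthetic survey world
(the generator is deterministic, so stages agree across scripts without
serializing multi-megabase state) and writes its tables under results/.
Default scale is a 1 Mb arm pair — a desk-scale survey that runs each
stage in seconds; the acceptance suite runs the full 5 Mb configuration.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def parse_args(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--arm-len", type=int, default=1_000_000,
                    help="length of each simulated arm (bp)")
    return ap.parse_args()


def get_world(args):
    from chromosurvey.simulate import SimulationConfig, simulate_survey
    cfg = SimulationConfig(seed=args.seed,
                           arm_len={"S": args.arm_len, "L": args.arm_len})
    return simulate_survey(cfg)


def outdir():
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
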