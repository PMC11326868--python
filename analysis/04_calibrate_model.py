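"""Run the full MOC-model calibration pipeline from scratch and regenerate
the shipped channel/mini parameters (src/mocsyn/data/calibrated.yaml).

Stages: subthreshold densities (evoked decay-tau minimax) -> spiking
densities (train AP targets, grid + Nelder-Mead) -> mini synapse parameters.
This is the slow, full-fidelity run (~30-60 min); the shipped YAML is its
frozen output, and `--quick` runs a reduced-budget version for smoke checks
without overwriting the shipped file.
"""

import argparse
import dataclasses
import json
import pathlib

import yaml

from mocsyn.experiments import calibrate_model

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
DATA = ROOT / "src" / "mocsyn" / "data" / "calibrated.yaml"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true",
                    help="reduced optimizer budgets; do not overwrite the "
                         "shipped calibration")
    ap.add_argument("--write", action="store_true",
                    help="overwrite src/mocsyn/data/calibrated.yaml")
    args = ap.parse_args()

    kw = {}
    if args.quick:
        kw = dict(subthreshold_kw=dict(maxfev=15), spiking_kw=dict(
            maxfev=5, grid=[(-1.67, -2.85, -3.55)]), minis_kw=dict(maxfev=20),
            outer_iters=1)
    result = calibrate_model(verbose=True, **kw)

    OUT.mkdir(exist_ok=True)
    with open(OUT / "calibration_report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, default=float)
    key, worst = result.worst_residual
    print(f"worst residual: {key} = {worst:+.1%}")
    for k, v in sorted(result.report["residuals"].items()):
        print(f"  {k:28s} {v:+.1%}")

    if args.write and not args.quick:
        doc = {
            "channels": dataclasses.asdict(result.channels),
            "minis": result.minis,
            "holding": {"target_mV": -60.0},
            "provenance": "produced by analysis/04_calibrate_model.py",
        }
        with open(DATA, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        print(f"wrote {DATA}")


if __name__ == "__main__":
    main()
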