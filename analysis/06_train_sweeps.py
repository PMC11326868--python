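"""Run the 100 Hz train protocols on the calibrated model: EPSP-only,
control (+2.8 ms E-I latency), the full E-I latency sweep at full IPSP
weight and at the 0.51 depression scale, and the single-PSP latency sweep.

Writes results/train_sweep.tsv (both IPSP scales) and
results/single_psp_sweep.tsv.
"""

import pathlib

import pandas as pd

from mocsyn import io
from mocsyn.experiments import (
    IPSP_DEPRESSION_SCALE,
    TrainProtocol,
    default_model,
    run_ei_single_sweep,
    run_ei_train_sweep,
    run_train,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    model = default_model()
    e_only = run_train(model, TrainProtocol(include_ipsp=False))
    ctrl = run_train(model, TrainProtocol())
    print(f"EPSP-only train: {e_only.n_aps} APs, first at "
          f"{e_only.first_latency_ms:.1f} ms, rate {e_only.rate_hz:.1f} Hz")
    print(f"control (+2.8 ms) train: {ctrl.n_aps} APs, first at "
          f"{ctrl.first_latency_ms and round(ctrl.first_latency_ms, 1)} ms, "
          f"rate {ctrl.rate_hz:.1f} Hz")

    frames = []
    for scale in (1.0, IPSP_DEPRESSION_SCALE):
        rows = run_ei_train_sweep(model, ipsp_scale=scale)
        df = pd.DataFrame(rows)
        df["ipsp_scale"] = scale
        frames.append(df)
        with_i = df[df.delta.notna()]
        print(f"ipsp_scale {scale}: rates "
              f"{with_i.rate_hz.min():.1f}-{with_i.rate_hz.max():.1f} Hz, "
              f"latencies {with_i.latency_ms.min():.1f}-"
              f"{with_i.latency_ms.max():.1f} ms across deltas")
    io.save_table(OUT / "train_sweep.tsv", pd.concat(frames, ignore_index=True))

    amps = run_ei_single_sweep(model)
    io.save_table(
        OUT / "single_psp_sweep.tsv",
        pd.DataFrame({"delta_ms": list(amps), "peak_depol_mV": list(amps.values())}),
    )
    worst = min(amps, key=amps.get)
    print(f"single-PSP sweep: peak depolarization minimized at delta "
          f"{worst:+.0f} ms ({amps[worst]:.2f} mV)")


if __name__ == "__main__":
    main()
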