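"""Simulate the calibrated model's single evoked PSPs (control, EPSP-only,
IPSP-only) and its mini PSPs, and tabulate amplitudes and decay constants.

Writes results/evoked_psps.tsv.
"""

import pathlib

import pandas as pd

from mocsyn import io
from mocsyn.experiments import default_model, run_evoked_psp
from mocsyn.metrics import measure_psp
from mocsyn.model import SynapseSpec

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    model = default_model()
    rows = []
    for cond in ("control", "epsp_only", "ipsp_only"):
        p = run_evoked_psp(model, cond)
        rows.append(dict(protocol=f"evoked_{cond}", amplitude_mV=p.amplitude_mV,
                         decay_tau_ms=p.decay_tau_ms))
        print(f"evoked {cond:10s}: {p.amplitude_mV:+.3f} mV, "
              f"tau {p.decay_tau_ms and round(p.decay_tau_ms, 2)} ms")
    for name, params in model.minis.items():
        syn = SynapseSpec(onset=20.0, **params)
        res = model.run_protocol([syn], duration=140.0, dt=0.025)
        p = measure_psp(res, onset=20.0)
        rows.append(dict(protocol=f"mini_{name}", amplitude_mV=p.amplitude_mV,
                         decay_tau_ms=p.decay_tau_ms))
        print(f"mini {name:6s}: {p.amplitude_mV:+.3f} mV, "
              f"tau {p.decay_tau_ms and round(p.decay_tau_ms, 2)} ms")
    io.save_table(OUT / "evoked_psps.tsv", pd.DataFrame(rows))


if __name__ == "__main__":
    main()
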