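"""Generate the synthetic PSC sweep sets used by the detection/clustering
analyses: one cell recorded at -60 mV (E+I inward) and at 0 mV (I outward),
with the midline-stimulation cluster geometry, plus the ground-truth tables.

Writes results/sweeps_minus60.h5, results/sweeps_0mV.h5 and the truth TSVs.
"""

import pathlib

from mocsyn import io
from mocsyn.synth import (
    EXCITATORY_CLUSTER,
    INHIBITORY_CLUSTER,
    SweepGenSpec,
    generate_sweep_set,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    for tag, holding, seed in [("minus60", -60.0, 101), ("0mV", 0.0, 102)]:
        spec = SweepGenSpec(
            n_sweeps=60, duration=40.0, stim_times=(10.0,),
            clusters=(EXCITATORY_CLUSTER, INHIBITORY_CLUSTER),
            holding_potential=holding, noise_rms=1.0, seed=seed,
        )
        sweeps, truth = generate_sweep_set(spec)
        io.save_sweep_set(OUT / f"sweeps_{tag}.h5", sweeps)
        io.save_table(OUT / f"truth_{tag}.tsv", truth)
        io.save_sweep_spec(OUT / f"sweep_spec_{tag}.yaml", spec)
        print(f"{tag}: {sweeps.n_sweeps} sweeps, {len(truth)} true events "
              f"({truth.label.value_counts().to_dict()})")


if __name__ == "__main__":
    main()
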