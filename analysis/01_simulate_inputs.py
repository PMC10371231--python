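"""Generate the study's synthetic inputs: a tracer phantom, an ICP trace, TSCs.

Writes a ground-truthed DCE phantom (constant bulk flow, 32^3 grid at
0.3 mm, 5 frames at 5-min spacing), a two-epoch 10 kHz ICP trace (baseline
and a raised-pulse-amplitude epoch mimicking airway pressurisation), and
noisy gamma-variate lymph-node uptake curves peaking near 87 min.
Everything downstream (02-05) can be regenerated from these seeds.
"""

from pathlib import Path

import numpy as np

from glymphflow import io as gio
from glymphflow.icp import ICPRecording
from glymphflow.synthetic import (
    BolusSpec,
    ICPSpec,
    PhantomSpec,
    make_icp_waveform,
    make_tsc,
    make_velocity_field,
    simulate_tracer_series,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SEED = 20251001


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = PhantomSpec(
        seed=SEED,
        bolus=BolusSpec(center_mm=(3.6, 4.8, 4.8), width_mm=0.9, amplitude=30.0),
    )
    truth = make_velocity_field(spec)
    series = simulate_tracer_series(spec, truth)
    gio.save_series(OUT / "phantom.nii.gz", series)
    gio.save_json(
        OUT / "phantom_ground_truth.json",
        {
            "expected_mean_speed_um_s": truth.expected_mean_speed_um_s,
            "sigma_true_mm2_s": truth.sigma_true_mm2_s,
            "velocity_magnitude_mm_per_interval": spec.velocity_magnitude,
        },
    )
    print(
        f"phantom: {spec.grid_dims} voxels, {spec.n_frames} frames, "
        f"true mean speed {truth.expected_mean_speed_um_s:.3f} um/s"
    )

    base = ICPSpec(duration_s=30.0, seed=SEED)
    cpap = ICPSpec(duration_s=30.0, baseline_mmhg=6.7, cardiac_amp_mmhg=0.45, seed=SEED + 1)
    rec = ICPRecording(
        np.concatenate(
            [make_icp_waveform(base).samples_mmhg, make_icp_waveform(cpap).samples_mmhg]
        ),
        base.sampling_rate_hz,
        epochs={"baseline": (0.0, 30.0), "cpap": (30.0, 60.0)},
    )
    gio.save_icp_csv(OUT / "icp_trace.csv", rec)
    gio.save_json(OUT / "icp_epochs.json", rec.epochs)
    print("icp trace: 60 s at 10 kHz, baseline + raised-pulse epoch")

    times = np.arange(0.0, 180.0, 5.0)
    for i in range(6):
        tsc = make_tsc(
            times, t0_min=10.0, t_peak_min=87.0, alpha=6.0, amplitude=0.13,
            noise_sd=0.05 * 0.13, seed=SEED + i,
        )
        gio.save_tsc_csv(OUT / f"tsc_dcln_{i:02d}.csv", tsc)
    print("tsc: 6 noisy dcLN curves, true peak at 87 min")


if __name__ == "__main__":
    main()
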