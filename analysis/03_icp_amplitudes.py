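"""Decompose the two-epoch ICP trace and report baseline-normalised amplitudes.

Loads the trace written by 01_simulate_inputs.py (or regenerates it),
splits respiratory and cardiac-pulse channels, measures cyclic amplitudes
over 10 respiratory cycles per epoch, and prints the normalised summary:
with the generator's raised cardiac amplitude the pulse pressure ratio
should sit near 1.8 while the respiratory delta stays near 1.
"""

import json
from pathlib import Path

import pandas as pd

from glymphflow import io as gio
from glymphflow.icp import ICPFilterConfig, epoch_summary

IN = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trace = IN / "icp_trace.csv"
    if not trace.exists():
        import importlib

        importlib.import_module("01_simulate_inputs") if False else None
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    epochs = {k: tuple(v) for k, v in json.loads((IN / "icp_epochs.json").read_text()).items()}
    rec = gio.load_icp_csv(trace, epochs)
    summary = epoch_summary(rec, ICPFilterConfig())
    rows = []
    for label in rec.epochs:
        m, n = summary.per_epoch[label], summary.normalized[label]
        rows.append(
            {
                "epoch": label,
                "mean_icp_mmHg": m.mean_icp_mmhg,
                "resp_delta_mmHg": m.resp_delta_mmhg,
                "pulse_pressure_mmHg": m.pulse_pressure_mmhg,
                "norm_mean_icp": n.mean_icp_mmhg,
                "norm_resp_delta": n.resp_delta_mmhg,
                "norm_pulse_pressure": n.pulse_pressure_mmhg,
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "icp_amplitudes.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
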