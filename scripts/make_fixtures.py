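"""Regenerate the shipped example datasets under fixtures/.

Each dataset comes from the default two-condition scenario (true
modulations 0, +0.1, -0.4, -0.4 on the four TPJ<->FEF connections) with its
generating seed recorded in ground_truth.json, so every fixture can be
rebuilt bit-identically:

    python scripts/make_fixtures.py
"""

from pathlib import Path

import numpy as np

from erpdcm.simulate import save_sensor_data
from erpdcm.synth import default_scenario, generate_dataset

ROOT = Path(__file__).resolve().parent.parent / "fixtures"

DATASETS = {
    "two_condition_noiseless": dict(snr_db=np.inf, seed=0),
    "two_condition_10db": dict(snr_db=10.0, seed=101),
}


def main() -> None:
    spec, params, _ = default_scenario()
    for name, kw in DATASETS.items():
        data, truth = generate_dataset(spec, params, **kw)
        out = ROOT / name
        save_sensor_data(data, out)
        truth.to_json(out / "ground_truth.json")
        print(f"wrote {out} (snr={kw['snr_db']}, seed={kw['seed']})")


if __name__ == "__main__":
    main()
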