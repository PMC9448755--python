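#!/usr/bin/env python
"""Derive the ten bioclimatic predictors cell-wise from the monthly cube."""

from pathlib import Path

import numpy as np

from paleopop import io as pio
from paleopop.cli import stage_derive
from paleopop.config import load_config

HERE = Path(__file__).resolve().parent


def main():
    cfg = load_config(HERE / "config_synthetic.yml")
    out = Path(cfg.out_dir)
    stage_derive(cfg, out)
    pred = pio.read_climate_cube(out / "predictor_cube.nc", monthly=False)
    print(f"Predictor cube written to {out}/predictor_cube.nc")
    print("Continental ranges over all time steps:")
    for v in cfg.variables:
        vals = pred[v].values
        print(f"  {v:8s} {np.nanmin(vals):8.2f} .. {np.nanmax(vals):8.2f}")


if __name__ == "__main__":
    main()
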