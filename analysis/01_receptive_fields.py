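"""Map receptive fields from simulated probe sessions and fit 2D Gaussians.

Simulates a 9 x 9 probe-grid session for an 8-channel array, builds each
channel's baseline-subtracted response grid, fits the RF Gaussian, and
summarizes how well the known RF centres/widths are recovered.
Writes results/rf_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from facecontext import experiments, mapping, simulator

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

array = simulator.make_array(n_channels=8, center=(1.0, -0.5), seed=0)
record, protocol, _ = simulator.simulate_probe_session(
    array, grid_shape=9, spacing_deg=1.0, reps=10, seed=1)

rows = []
for ch, cell in zip(record.channels, array.channels):
    grid = mapping.probe_response_grid(record, protocol, ch)
    fit = mapping.fit_rf_gaussian(grid, independent_sigma=False)
    rows.append({
        "channel": ch,
        "true_x": cell.rf_center_deg[0], "true_y": cell.rf_center_deg[1],
        "fit_x": fit.centroid_deg[0], "fit_y": fit.centroid_deg[1],
        "true_sigma": cell.rf_sigma_deg, "fit_sigma": fit.sigma_deg[0],
        "amplitude_hz": fit.amplitude_hz, "goodness": fit.goodness,
    })
fits = pd.DataFrame(rows)
fits.to_csv(OUT / "rf_fits.csv", index=False, float_format="%.4g")

err = np.hypot(fits.fit_x - fits.true_x, fits.fit_y - fits.true_y)
print(f"fitted {len(fits)} channels; median centroid error "
      f"{err.median():.3f} deg, median |sigma| error "
      f"{(fits.fit_sigma - fits.true_sigma).abs().median():.3f} deg")

rec = experiments.rf_recovery_experiment(n_runs=50, seed=2)
print(f"recovery across 50 seeded sessions: centroid within 0.25 deg and "
      f"sigma within 20% in {rec['fraction_ok']:.0%} of runs")
print(f"wrote {OUT / 'rf_fits.csv'}")
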