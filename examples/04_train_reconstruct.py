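"""Tiny end-to-end run: simulate, preprocess, train, reconstruct, score.

Generates 8 phantoms on a reduced mesh, simulates their multistatic
signals, trains the encoder-decoder for a short burst at 32x32 resolution,
and scores the fitted reconstructions. This is a scaled-down demonstration
of the full pipeline (the paper-scale run uses 25,000 cases at 256x256);
expect the training loss to fall sharply and the fitted SSIM to be well
above the all-background baseline. Runtime is a few minutes on one CPU.
"""

import numpy as np

from mwtomo import AntennaArray, DomainConfig, SolverConfig
from mwtomo.fdtd import design_pulse, run_multistatic
from mwtomo.metrics import evaluate_case, ssim, summarize
from mwtomo.nn import NetworkConfig, TrainConfig, UNet, predict, train
from mwtomo.phantoms import generate_database
from mwtomo.pipeline import preprocess

domain = DomainConfig(cell_size=4.0)
solver = SolverConfig(dx=4e-3, dt=23.6e-12, n_steps=1000)
array = AntennaArray.from_domain(domain)
pulse = design_pulse(solver.band_low, solver.band_high, solver.dt, solver.n_steps)

xs, ys, ids = [], [], []
for case in generate_database(8, domain, seed=3, grouped=False, n_shapes=4):
    tensor = run_multistatic(case, array, solver, pulse)
    imap = preprocess(tensor, rate=4, n_pad=6)
    xs.append(imap.values.reshape(32, 8, 32, 8).mean(axis=(1, 3)))
    ys.append(case.label_eps.reshape(32, 8, 32, 8).mean(axis=(1, 3)))
    ids.append(case.case_id)
    print(f"simulated {case.case_id}")
x, y = np.stack(xs), np.stack(ys)

net = UNet(NetworkConfig(encoder_channels=(4, 8, 16, 32, 64)), seed=0)
cfg = TrainConfig(batch_size=8, n_steps=1500, seed=0)
history = train(net, x, y, cfg)
print(f"training MSE: {history[0]:.4f} -> {history[-1]:.4f} "
      f"({history[0] / history[-1]:.0f}x reduction)")

preds = predict(net, x, cfg)
records = [evaluate_case(i, p, t) for i, p, t in zip(ids, preds, y)]
summary = summarize(records)
baseline = float(np.mean([ssim(np.full_like(t, 40.0), t) for t in y]))
print(f"fitted mean SSIM {summary.ssim_mean:.3f} "
      f"(all-background baseline {baseline:.3f}), "
      f"mean NRMSE {summary.nrmse_mean:.3f}, mean PSNR {summary.psnr_mean:.1f} dB")
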