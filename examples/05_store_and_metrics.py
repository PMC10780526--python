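"""Persist cases to HDF5, split them, and summarize evaluation metrics.

Writes a few phantoms (with synthetic stand-in reconstruction results) to a
case store, builds a seeded train/test manifest, and prints a Table-style
metric summary: mean, proportion meeting the accepted-quality baseline
(SSIM > 0.9, NRMSE < 0.2, PSNR > 30 dB), and standard deviation.
"""

import tempfile
from pathlib import Path

import h5py
import numpy as np

from mwtomo import DomainConfig
from mwtomo.metrics import evaluate_case, summarize
from mwtomo.phantoms import generate_database
from mwtomo.store import list_cases, load_case, save_case, split_dataset

workdir = Path(tempfile.mkdtemp())
store_path = workdir / "demo.h5"
cfg = DomainConfig(cell_size=4.0)

cases = list(generate_database(10, cfg, seed=5, grouped=False, n_shapes=3))
with h5py.File(store_path, "w") as store:
    for case in cases:
        save_case(store, case, seed=5, config_hash="demo")
    print(f"stored {len(list_cases(store))} cases in {store_path}")

manifest = split_dataset([c.case_id for c in cases], seed=5, train_fraction=0.8)
print(f"split: {len(manifest.train_ids)} train / {len(manifest.test_ids)} test")

# score noisy stand-in "reconstructions" against the stored ground truths
rng = np.random.default_rng(0)
records = []
with h5py.File(store_path, "r") as store:
    for cid in manifest.test_ids:
        case, _, _ = load_case(store, cid)
        fake_recon = case.label_eps + rng.normal(0, 2.0, case.label_eps.shape)
        records.append(evaluate_case(cid, fake_recon, case.label_eps))

s = summarize(records)
print(f"SSIM  mean {s.ssim_mean:.4f}  >0.9 {s.ssim_above_09:.0%}  std {s.ssim_std:.4f}")
print(f"NRMSE mean {s.nrmse_mean:.4f}  <0.2 {s.nrmse_below_02:.0%}  std {s.nrmse_std:.4f}")
print(f"PSNR  mean {s.psnr_mean:.2f} dB  >30 {s.psnr_above_30:.0%}  std {s.psnr_std:.4f}")
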