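"""End-to-end orchestration: phantoms -> FDTD -> preprocessing -> store.

These functions tie the stages together at any scale — the full database
layout (25,000 cases, ten groups, 24,000/1,000 split) or a reduced-mesh
smoke run — with one seed controlling everything and every artifact
carrying the config hash that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np

from . import metrics as _metrics
from .config import DomainConfig, SolverConfig, config_hash
from .fdtd import AntennaArray, design_pulse, run_multistatic
from .phantoms import generate_database
from .pipeline import preprocess
from .store import DatasetManifest, load_case, save_case, split_dataset

log = logging.getLogger("mwtomo")


@dataclass(frozen=True)
class PipelineConfig:
    """Scale knobs for a dataset production run."""

    n_cases: int = 10
    seed: int = 0
    grouped: bool = True
    n_shapes: int | None = None      # fixed count when grouped=False
    downsample_rate: int = 20
    n_pad: int = 6
    train_fraction: float = 0.96     # 24,000 / 25,000


def generate_dataset(
    path,
    domain: DomainConfig,
    solver: SolverConfig,
    pcfg: PipelineConfig,
    simulate: bool = True,
) -> DatasetManifest:
    """Generate phantoms (and optionally signals + input maps) into HDF5.

    Deterministic per seed: the same call yields byte-identical arrays.
    Returns the train/test manifest, also stored as a JSON string attribute
    on the file root.
    """
    chash = config_hash(domain, solver, pcfg)
    array = AntennaArray.from_domain(domain)
    pulse = design_pulse(solver.band_low, solver.band_high, solver.dt, solver.n_steps)
    rate = pcfg.downsample_rate

    with h5py.File(path, "a") as store:
        case_ids = []
        for case in generate_database(
            pcfg.n_cases, domain, pcfg.seed,
            grouped=pcfg.grouped, n_shapes=pcfg.n_shapes,
        ):
            signals = imap = None
            if simulate:
                signals = run_multistatic(case, array, solver, pulse)
                imap = preprocess(signals, rate=rate, n_pad=pcfg.n_pad)
            save_case(store, case, signals, imap, seed=pcfg.seed, config_hash=chash)
            case_ids.append(case.case_id)
            log.info("generated %s (%d shapes)", case.case_id, case.group_index)

        manifest = split_dataset(
            case_ids, seed=pcfg.seed, train_fraction=pcfg.train_fraction,
            config_hash=chash,
        )
        store.attrs["config_hash"] = chash
        store.attrs["n_cases"] = len(case_ids)
    return manifest


def load_training_arrays(
    path, case_ids: list[str], label_resolution: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(inputs, labels) stacks for the listed cases.

    ``label_resolution`` block-averages labels and strides input maps down to
    a reduced square size for CPU-scale training.
    """
    xs, ys = [], []
    with h5py.File(path, "r") as store:
        for cid in case_ids:
            case, _, imap = load_case(store, cid)
            if imap is None:
                raise ValueError(f"case {cid} has no input_map")
            x = imap.values
            y = case.label_eps
            if label_resolution is not None and label_resolution != y.shape[0]:
                f = y.shape[0] // label_resolution
                y = y.reshape(label_resolution, f, label_resolution, f).mean(axis=(1, 3))
                fx = x.shape[0] // label_resolution
                x = x[::fx, ::fx]
            xs.append(x)
            ys.append(y)
    return np.stack(xs), np.stack(ys)


def evaluate_predictions(
    case_ids: list[str], predictions: np.ndarray, references: np.ndarray
) -> tuple[list[_metrics.EvalRecord], _metrics.EvalSummary]:
    """Per-case SSIM/NRMSE/PSNR records plus the dataset summary."""
    records = [
        _metrics.evaluate_case(cid, pred, ref)
        for cid, pred, ref in zip(case_ids, predictions, references)
    ]
    return records, _metrics.summarize(records)
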