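"""HDF5 case store, dataset manifests and train/test splitting.

One HDF5 file per dataset, one group per case (``/cases/<case_id>``)
holding the phantom maps, the ground-truth label, optionally the raw
signal tensor and the preprocessed input map, plus provenance attributes
(seed, config hash, schema version). Writes are atomic per case so a
partially generated database can be resumed or extended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .config import ConfigError
from .fdtd import SignalTensor
from .phantoms import PhantomCase, ShapeSpec
from .pipeline import InputMap

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Store contents do not match the expected schema."""


@dataclass(frozen=True)
class DatasetManifest:
    """Ordered case ids with their seeded train/test assignment."""

    case_ids: tuple[str, ...]
    split_assignment: dict[str, str]
    seed: int
    config_hash: str = ""
    group_sizes: tuple[int, ...] = ()

    @property
    def train_ids(self) -> list[str]:
        return [c for c in self.case_ids if self.split_assignment[c] == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [c for c in self.case_ids if self.split_assignment[c] == "test"]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "case_ids": list(self.case_ids),
                    "split_assignment": self.split_assignment,
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "group_sizes": list(self.group_sizes),
                    "schema_version": SCHEMA_VERSION,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise FormatError(f"manifest schema {d.get('schema_version')} != {SCHEMA_VERSION}")
        return cls(
            case_ids=tuple(d["case_ids"]),
            split_assignment=d["split_assignment"],
            seed=d["seed"],
            config_hash=d["config_hash"],
            group_sizes=tuple(d["group_sizes"]),
        )


def split_dataset(
    case_ids: list[str],
    seed: int,
    n_train: int | None = None,
    n_test: int | None = None,
    train_fraction: float | None = None,
    config_hash: str = "",
    group_sizes: tuple[int, ...] = (),
) -> DatasetManifest:
    """Seeded shuffle followed by a train/test partition.

    At the database defaults 25,000 cases split 24,000/1,000. Either exact
    counts or a ``train_fraction`` may be given.
    """
    n = len(case_ids)
    if train_fraction is not None:
        if not (0.0 <= train_fraction <= 1.0):
            raise ConfigError("train_fraction must be in [0, 1]")
        n_train = round(n * train_fraction)
        n_test = n - n_train
    if n_train is None or n_test is None or n_train + n_test != n or n_train < 0:
        raise ConfigError(
            f"split counts ({n_train}, {n_test}) inconsistent with {n} cases"
        )
    rng = np.random.default_rng(seed)
    shuffled = [case_ids[i] for i in rng.permutation(n)]
    assignment = {c: ("train" if i < n_train else "test") for i, c in enumerate(shuffled)}
    return DatasetManifest(
        case_ids=tuple(case_ids),
        split_assignment=assignment,
        seed=seed,
        config_hash=config_hash,
        group_sizes=group_sizes,
    )


_SHAPE_FIELDS = [
    "kind", "cx", "cy", "major_axis", "minor_axis", "rotation",
    "eps_value", "sigma_value", "n_edges",
]


def _shapes_to_table(shapes: list[ShapeSpec]) -> tuple[np.ndarray, str]:
    """Shape list as a numeric table + JSON sidecar for polygon angles."""
    rows = np.zeros((len(shapes), len(_SHAPE_FIELDS)))
    angles = []
    for i, s in enumerate(shapes):
        rows[i] = [
            0 if s.kind == "ellipse" else 1, s.center[0], s.center[1],
            s.major_axis, s.minor_axis, s.rotation, s.eps_value, s.sigma_value,
            -1 if s.n_edges is None else s.n_edges,
        ]
        angles.append(list(s.vertex_angles) if s.vertex_angles else None)
    return rows, json.dumps(angles)


def _table_to_shapes(rows: np.ndarray, angles_json: str) -> list[ShapeSpec]:
    angles = json.loads(angles_json)
    shapes = []
    for r, ang in zip(rows, angles):
        kind = "ellipse" if r[0] == 0 else "polygon"
        shapes.append(
            ShapeSpec(
                kind=kind, center=(float(r[1]), float(r[2])),
                major_axis=float(r[3]), minor_axis=float(r[4]),
                rotation=float(r[5]), eps_value=float(r[6]),
                sigma_value=float(r[7]),
                n_edges=None if r[8] < 0 else int(r[8]),
                vertex_angles=None if ang is None else tuple(ang),
            )
        )
    return shapes


def save_case(
    store: h5py.File,
    case: PhantomCase,
    signals: SignalTensor | None = None,
    input_map: InputMap | None = None,
    seed: int | None = None,
    config_hash: str = "",
) -> None:
    """Write one case group (replacing any existing group of the same id)."""
    root = store.require_group("cases")
    if case.case_id in root:
        del root[case.case_id]
    g = root.create_group(case.case_id)
    g.create_dataset("eps_map", data=case.eps_map)
    g.create_dataset("sigma_map", data=case.sigma_map)
    g.create_dataset("label_eps", data=case.label_eps)
    table, angles = _shapes_to_table(case.shapes)
    g.create_dataset("shapes", data=table)
    g.attrs["shape_angles"] = angles
    g.attrs["group_index"] = case.group_index
    g.attrs["schema_version"] = SCHEMA_VERSION
    g.attrs["config_hash"] = config_hash
    if seed is not None:
        g.attrs["seed"] = seed
    if signals is not None:
        g.create_dataset("signals", data=signals.data)
    if input_map is not None:
        g.create_dataset("input_map", data=input_map.values)


def load_case(
    store: h5py.File, case_id: str
) -> tuple[PhantomCase, SignalTensor | None, InputMap | None]:
    """Lossless inverse of :func:`save_case`."""
    try:
        g = store["cases"][case_id]
    except KeyError as exc:
        raise FormatError(f"case {case_id!r} not in store") from exc
    if g.attrs.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"case {case_id!r}: schema {g.attrs.get('schema_version')} != {SCHEMA_VERSION}"
        )
    for name in ("eps_map", "sigma_map", "label_eps", "shapes"):
        if name not in g:
            raise FormatError(f"case {case_id!r}: missing dataset {name!r}")
    case = PhantomCase(
        case_id=case_id,
        shapes=_table_to_shapes(g["shapes"][...], g.attrs["shape_angles"]),
        eps_map=g["eps_map"][...],
        sigma_map=g["sigma_map"][...],
        label_eps=g["label_eps"][...],
        group_index=int(g.attrs["group_index"]),
    )
    signals = SignalTensor(data=g["signals"][...]) if "signals" in g else None
    imap = InputMap(values=g["input_map"][...]) if "input_map" in g else None
    return case, signals, imap


def list_cases(store: h5py.File) -> list[str]:
    if "cases" not in store:
        return []
    return sorted(store["cases"].keys())


def export_label_png(label_eps: np.ndarray, path, eps_range=(10.0, 80.0)) -> None:
    """8-bit PNG of a label image (visual inspection only)."""
    import imageio.v3 as iio

    lo, hi = eps_range
    img = np.clip((label_eps - lo) / (hi - lo), 0, 1)
    iio.imwrite(path, (img * 255).astype(np.uint8))
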