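"""Reading and writing 2D landmark data.

Supports the TPS text dialect emitted by the tpsUtil/tpsDig tool chain
(records introduced by ``LM=<k>``, followed by ``k`` whitespace-separated
coordinate rows and optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines) and a
long-format coordinate table (one row per landmark).  Also parses the
four-part dataset naming scheme ``<device>_<NoTilt|Tilted>_<observer>_T<n>``
used to label replicated acquisition runs.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkError",
    "TpsParseError",
    "DatasetError",
    "DatasetNameError",
    "LandmarkConfiguration",
    "AcquisitionLabel",
    "LandmarkDataset",
    "read_tps",
    "write_tps",
    "read_table",
    "write_table",
    "parse_dataset_name",
    "format_dataset_name",
]

DEVICE_DINOLITE = "Dinolite"
DEVICE_NIKON = "Nikon"


class LandmarkError(ValueError):
    """Base class for landmark data errors."""


class TpsParseError(LandmarkError):
    """Malformed TPS record."""


class DatasetError(LandmarkError):
    """Inconsistent landmark dataset."""


class DatasetNameError(LandmarkError):
    """Dataset name does not follow the four-part acquisition scheme."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered landmark configuration.

    ``coords`` is a ``(k, 2)`` array of (x, y) points in image units, or
    ``(k, 3)`` when a latent z (surface relief) is carried by synthetic
    configurations.  Landmark order is fixed and meaningful (homology).
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise LandmarkError(
                f"coords must be (k, 2) or (k, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise LandmarkError(
                f"configuration {self.specimen_id!r} needs k >= 3 landmarks"
            )
        if not np.all(np.isfinite(self.coords)):
            raise LandmarkError(
                f"configuration {self.specimen_id!r} has non-finite coordinates"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def is_3d(self) -> bool:
        return self.coords.shape[1] == 3

    @property
    def xy(self) -> np.ndarray:
        """The 2D (x, y) part of the configuration."""
        return self.coords[:, :2]


@dataclass(frozen=True)
class AcquisitionLabel:
    """Device / tilt / observer / trial tag of one data-acquisition run.

    Round-trips exactly through the underscore-joined dataset name, e.g.
    ``Dinolite_NoTilt_EO_T1``.
    """

    device: str
    tilted: bool
    observer: str
    trial: int

    def __post_init__(self) -> None:
        if self.trial < 1:
            raise DatasetNameError(f"trial must be a positive integer, got {self.trial}")

    @property
    def name(self) -> str:
        tilt = "Tilted" if self.tilted else "NoTilt"
        return f"{self.device}_{tilt}_{self.observer}_T{self.trial}"

    @classmethod
    def parse(cls, name: str) -> "AcquisitionLabel":
        fields = name.split("_")
        if len(fields) != 4:
            raise DatasetNameError(
                f"dataset name {name!r} must have 4 underscore-separated fields, "
                f"got {len(fields)}"
            )
        device, tilt, observer, trial = fields
        if tilt not in ("NoTilt", "Tilted"):
            raise DatasetNameError(
                f"tilt field of {name!r} must be 'NoTilt' or 'Tilted', got {tilt!r}"
            )
        m = re.fullmatch(r"T(\d+)", trial)
        if m is None or int(m.group(1)) < 1:
            raise DatasetNameError(
                f"trial field of {name!r} must look like 'T1', got {trial!r}"
            )
        return cls(device=device, tilted=(tilt == "Tilted"), observer=observer,
                   trial=int(m.group(1)))


def parse_dataset_name(name: str) -> AcquisitionLabel:
    """Parse ``Device_Tilt_Observer_Tn`` into an :class:`AcquisitionLabel`."""
    return AcquisitionLabel.parse(name)


def format_dataset_name(label: AcquisitionLabel) -> str:
    """Inverse of :func:`parse_dataset_name`."""
    return label.name


class LandmarkDataset:
    """A set of same-k landmark configurations with optional species labels.

    Parameters
    ----------
    configurations
        Per-specimen :class:`LandmarkConfiguration`; specimen ids must be
        unique and all configurations must share the landmark count ``k``.
    species
        Optional per-specimen group labels, either a sequence aligned with
        ``configurations`` or a mapping from specimen id to label.
    label
        Optional :class:`AcquisitionLabel` identifying the acquisition run.
    """

    def __init__(self, configurations, species=None, label: AcquisitionLabel | None = None):
        self.configurations = list(configurations)
        if not self.configurations:
            self.species = None
            self.label = label
            return
        ks = {c.k for c in self.configurations}
        if len(ks) != 1:
            raise DatasetError(f"inconsistent landmark counts across records: {sorted(ks)}")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate specimen ids: {dupes}")
        if isinstance(species, dict):
            missing = [i for i in ids if i not in species]
            if missing:
                raise DatasetError(f"species labels missing for specimens: {missing}")
            species = [species[i] for i in ids]
        elif species is not None:
            species = list(species)
            if len(species) != len(ids):
                raise DatasetError(
                    f"{len(species)} species labels for {len(ids)} configurations"
                )
        self.species = species
        self.label = label

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        if not self.configurations:
            raise DatasetError("empty dataset has no landmark count")
        return self.configurations[0].k

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def name(self) -> str | None:
        return self.label.name if self.label is not None else None

    def coords_array(self) -> np.ndarray:
        """Stack the 2D coordinates into an ``(n, k, 2)`` array."""
        return np.stack([c.xy for c in self.configurations])

    def species_of(self, specimen_id: str) -> str | None:
        if self.species is None:
            return None
        return self.species[self.specimen_ids.index(specimen_id)]

    def reordered(self, ids) -> "LandmarkDataset":
        """Return a copy with configurations in the order given by ``ids``."""
        index = {c.specimen_id: i for i, c in enumerate(self.configurations)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise DatasetError(f"specimens not in dataset: {missing}")
        rows = [index[i] for i in ids]
        sp = [self.species[r] for r in rows] if self.species is not None else None
        return LandmarkDataset([self.configurations[r] for r in rows], sp, self.label)


# ---------------------------------------------------------------------------
# TPS dialect

_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path, apply_scale: bool = True, flip_y: bool = False) -> LandmarkDataset:
    """Read a TPS file into a :class:`LandmarkDataset`.

    ``SCALE=`` records, when present, are multiplied into the raw pixel
    coordinates by default so that configurations from different imaging
    set-ups are in comparable physical units (``apply_scale=False`` keeps raw
    pixels).  Coordinates are stored as written; ``flip_y=True`` negates y for
    image-origin conventions.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if m is None or m.group(1).upper() != "LM":
            raise TpsParseError(
                f"record {record_index}: expected 'LM=<k>' line, got {line!r}"
            )
        try:
            k = int(m.group(2))
        except ValueError as exc:
            raise TpsParseError(f"record {record_index}: bad LM count {m.group(2)!r}") from exc
        i += 1
        pts = []
        while i < len(lines) and len(pts) < k:
            row = lines[i].strip()
            i += 1
            if not row:
                continue
            if _KEY_RE.match(row) and not re.match(r"^[-+0-9.]", row):
                break  # a key line arrived before k coordinate rows
            parts = row.split()
            if len(parts) < 2:
                raise TpsParseError(f"record {record_index}: bad coordinate row {row!r}")
            pts.append((float(parts[0]), float(parts[1])))
        if len(pts) != k:
            raise TpsParseError(
                f"record {record_index}: LM={k} but found {len(pts)} coordinate rows"
            )
        keys: dict[str, str] = {}
        while i < len(lines):
            nxt = lines[i].strip()
            if not nxt:
                i += 1
                continue
            km = _KEY_RE.match(nxt)
            if km is None:
                raise TpsParseError(f"record {record_index}: unexpected line {nxt!r}")
            if km.group(1).upper() == "LM":
                break
            keys[km.group(1).upper()] = km.group(2)
            i += 1

        coords = np.asarray(pts, dtype=float)
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        scale = float(keys["SCALE"]) if "SCALE" in keys else None
        if scale is not None and apply_scale:
            coords = coords * scale
        if "ID" in keys and keys["ID"]:
            sid = keys["ID"]
        elif "IMAGE" in keys and keys["IMAGE"]:
            sid = os.path.splitext(os.path.basename(keys["IMAGE"]))[0]
        else:
            sid = str(record_index)
        configs.append(LandmarkConfiguration(sid, coords, scale=scale))
        record_index += 1

    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset as TPS records (6 significant digits)."""
    with open(path, "w") as fh:
        for config in dataset:
            fh.write(f"LM={config.k}\n")
            for x, y in config.xy:
                fh.write(f"{x:.6g} {y:.6g}\n")
            fh.write(f"ID={config.specimen_id}\n")


# ---------------------------------------------------------------------------
# Long-format coordinate table

_TABLE_COLS = ["specimen_id", "landmark_index", "x", "y"]


def read_table(path_or_df) -> LandmarkDataset:
    """Read a long-format table (specimen_id, [species], landmark_index, x, y)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in _TABLE_COLS if c not in df.columns]
    if missing:
        raise DatasetError(f"table missing required columns: {missing}")
    has_species = "species" in df.columns

    configs = []
    species = [] if has_species else None
    expected = None
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("landmark_index")
        idx = tuple(grp["landmark_index"].tolist())
        if expected is None:
            expected = idx
        elif idx != expected:
            missing_lm = sorted(set(expected) - set(idx))
            raise DatasetError(
                f"specimen {sid!r} has inconsistent landmarks "
                f"(missing {missing_lm if missing_lm else 'none'}, found {list(idx)})"
            )
        configs.append(LandmarkConfiguration(str(sid), grp[["x", "y"]].to_numpy()))
        if has_species:
            sp = grp["species"].unique()
            if len(sp) != 1:
                raise DatasetError(f"specimen {sid!r} has conflicting species labels {list(sp)}")
            species.append(sp[0])
    return LandmarkDataset(configs, species=species)


def write_table(dataset: LandmarkDataset, path=None) -> pd.DataFrame:
    """Write a dataset as a long-format table; returns the DataFrame."""
    rows = []
    for i, config in enumerate(dataset):
        sp = dataset.species[i] if dataset.species is not None else None
        for j, (x, y) in enumerate(config.xy, start=1):
            row = {"specimen_id": config.specimen_id, "landmark_index": j,
                   "x": x, "y": y}
            if dataset.species is not None:
                row["species"] = sp
            rows.append(row)
    cols = ["specimen_id"] + (["species"] if dataset.species is not None else []) \
        + ["landmark_index", "x", "y"]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df
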