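"""Domain types and I/O for SMLM localization tables.

The primary data of single-molecule localization microscopy are not pixels
but a table with one row per detected emitter: spatial coordinates (nm),
per-axis localization precisions (nm, the standard deviation of the
coordinate estimate), and optionally a color channel, the acquisition frame
and the photon count.  :class:`LocalizationSet` is the in-memory container
for such a table; :class:`Site` is a bounded axis-aligned box containing the
localizations of a single biological structure ("particle").

Conventions
-----------
* all lengths in nm, right-handed coordinates, z = 0 at the focal plane;
* 0-based row indexing; site boxes are closed on all faces;
* CSV dialect: comma separated, ``.`` decimal, header row required.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationSet",
    "Site",
    "SchemaError",
    "ValidationError",
    "DEFAULT_COLUMNS",
    "read_localizations",
    "write_localizations",
    "crop_site",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A table row violates a localization-set invariant."""


#: default column names, overridable through ``column_map``
DEFAULT_COLUMNS = {
    "x": "x_nm",
    "y": "y_nm",
    "z": "z_nm",
    "sx": "sigma_x_nm",
    "sy": "sigma_y_nm",
    "sz": "sigma_z_nm",
    "channel": "channel",
    "frame": "frame",
    "photons": "photons",
}


@dataclass
class LocalizationSet:
    """A set of K localizations in D dimensions (D in {2, 3}).

    Parameters
    ----------
    coords : (K, D) float array
        Emitter coordinates in nm: columns x, y[, z].
    precisions : (K, D) float array
        Per-axis localization precision (standard deviation) in nm;
        strictly positive.
    channel : (K,) int array, optional
        Color label per localization; defaults to all zeros.
    frame : (K,) int array, optional
        Acquisition frame index.
    photons : (K,) float array, optional
        Photon count per localization.
    """

    coords: np.ndarray
    precisions: np.ndarray
    channel: np.ndarray | None = None
    frame: np.ndarray | None = None
    photons: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.precisions = np.atleast_2d(np.asarray(self.precisions, dtype=float))
        if self.coords.shape != self.precisions.shape:
            raise ValidationError(
                f"coords shape {self.coords.shape} != precisions shape "
                f"{self.precisions.shape}"
            )
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValidationError(
                f"coordinates must be (K, 2) or (K, 3), got {self.coords.shape}"
            )
        bad = np.flatnonzero(~(self.precisions > 0).all(axis=1))
        if bad.size:
            raise ValidationError(
                f"non-positive localization precision at row {bad[0]}"
            )
        if self.channel is None:
            self.channel = np.zeros(len(self.coords), dtype=int)
        else:
            self.channel = np.asarray(self.channel, dtype=int)
            if self.channel.shape != (len(self.coords),):
                raise ValidationError("channel must have one entry per row")
        for name in ("frame", "photons"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape != (len(self.coords),):
                    raise ValidationError(f"{name} must have one entry per row")
                setattr(self, name, val)

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_locs(self) -> int:
        """Number of localizations K."""
        return len(self.coords)

    @property
    def ndim(self) -> int:
        """Spatial dimensionality D (2 or 3)."""
        return self.coords.shape[1]

    @property
    def channels(self) -> np.ndarray:
        """Sorted unique channel labels."""
        return np.unique(self.channel)

    def select(self, mask: np.ndarray) -> "LocalizationSet":
        """Return the subset of rows where ``mask`` is true (or indexed)."""
        return LocalizationSet(
            coords=self.coords[mask],
            precisions=self.precisions[mask],
            channel=self.channel[mask],
            frame=None if self.frame is None else self.frame[mask],
            photons=None if self.photons is None else self.photons[mask],
        )

    def in_channel(self, c: int) -> "LocalizationSet":
        """Return the subset of localizations with channel label ``c``."""
        return self.select(self.channel == c)

    def with_coords(self, coords: np.ndarray) -> "LocalizationSet":
        """Copy of this set with coordinates replaced (precisions untouched)."""
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))

    def copy(self) -> "LocalizationSet":
        return LocalizationSet(
            coords=self.coords.copy(),
            precisions=self.precisions.copy(),
            channel=self.channel.copy(),
            frame=None if self.frame is None else self.frame.copy(),
            photons=None if self.photons is None else self.photons.copy(),
        )

    @staticmethod
    def concatenate(sets: list["LocalizationSet"]) -> "LocalizationSet":
        """Pool several localization sets (optional columns kept only if
        present in every member)."""
        if not sets:
            raise ValueError("cannot concatenate an empty list")
        frame = None
        if all(s.frame is not None for s in sets):
            frame = np.concatenate([s.frame for s in sets])
        photons = None
        if all(s.photons is not None for s in sets):
            photons = np.concatenate([s.photons for s in sets])
        return LocalizationSet(
            coords=np.concatenate([s.coords for s in sets], axis=0),
            precisions=np.concatenate([s.precisions for s in sets], axis=0),
            channel=np.concatenate([s.channel for s in sets]),
            frame=frame,
            photons=photons,
        )


@dataclass
class Site:
    """A bounded region containing one structure.

    ``localizations`` are stored *relative to* ``center``: the box of side
    ``side_length`` is centered at the origin of the stored coordinates, and
    closed on all faces.
    """

    localizations: LocalizationSet
    side_length: float
    center: np.ndarray
    id: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.side_length > 0:
            raise ValidationError("side_length must be > 0")
        self.center = np.asarray(self.center, dtype=float)
        half = self.side_length / 2
        coords = self.localizations.coords
        if coords.size and np.abs(coords).max() > half * (1 + 1e-12):
            raise ValidationError("localizations outside the site box")

    @property
    def ndim(self) -> int:
        return self.localizations.ndim

    @property
    def n_locs(self) -> int:
        return self.localizations.n_locs

    @property
    def volume(self) -> float:
        """Box volume d^D (area for D=2)."""
        return self.side_length**self.ndim


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _resolve_columns(column_map: dict | None) -> dict:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    return cols


def _table_from_locs(locs: LocalizationSet, cols: dict) -> pd.DataFrame:
    data = {cols["x"]: locs.coords[:, 0], cols["y"]: locs.coords[:, 1]}
    if locs.ndim == 3:
        data[cols["z"]] = locs.coords[:, 2]
    data[cols["sx"]] = locs.precisions[:, 0]
    data[cols["sy"]] = locs.precisions[:, 1]
    if locs.ndim == 3:
        data[cols["sz"]] = locs.precisions[:, 2]
    data[cols["channel"]] = locs.channel
    if locs.frame is not None:
        data[cols["frame"]] = locs.frame
    if locs.photons is not None:
        data[cols["photons"]] = locs.photons
    return pd.DataFrame(data)


def _locs_from_table(df: pd.DataFrame, cols: dict, source: str) -> LocalizationSet:
    for key in ("x", "y", "sx", "sy"):
        if cols[key] not in df.columns:
            raise SchemaError(f"{source}: missing required column '{cols[key]}'")
    is3d = cols["z"] in df.columns
    if is3d and cols["sz"] not in df.columns:
        raise SchemaError(f"{source}: column '{cols['z']}' present but "
                          f"'{cols['sz']}' missing")
    axes = ("x", "y", "z") if is3d else ("x", "y")
    saxes = ("sx", "sy", "sz") if is3d else ("sx", "sy")
    coords = np.column_stack([df[cols[a]].to_numpy(float) for a in axes])
    prec = np.column_stack([df[cols[a]].to_numpy(float) for a in saxes])
    channel = (df[cols["channel"]].to_numpy(int)
               if cols["channel"] in df.columns else None)
    frame = df[cols["frame"]].to_numpy() if cols["frame"] in df.columns else None
    photons = (df[cols["photons"]].to_numpy(float)
               if cols["photons"] in df.columns else None)
    return LocalizationSet(coords, prec, channel=channel, frame=frame,
                           photons=photons)


def read_localizations(path, format: str | None = None,
                       column_map: dict | None = None) -> LocalizationSet:
    """Read a localization table from CSV or HDF5.

    ``format`` is inferred from the file suffix when omitted.  HDF5 files
    store one dataset per column under the group ``localizations``.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    cols = _resolve_columns(column_map)
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            grp = f["localizations"]
            df = pd.DataFrame({name: grp[name][()] for name in grp})
    else:
        raise ValueError(f"unknown format {format!r}")
    return _locs_from_table(df, cols, str(path))


def write_localizations(locs: LocalizationSet, path, format: str | None = None,
                        column_map: dict | None = None) -> Path:
    """Write a localization table; round-trips bit-exactly through
    :func:`read_localizations`."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    cols = _resolve_columns(column_map)
    df = _table_from_locs(locs, cols)
    if format == "csv":
        # 17 significant digits keep the round trip bit exact
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("localizations")
            for name in df.columns:
                grp.create_dataset(name, data=df[name].to_numpy())
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def crop_site(locs: LocalizationSet, center, side_length: float,
              id=None) -> Site:
    """Crop the closed axis-aligned box of side ``side_length`` centered at
    ``center``; coordinates are re-expressed relative to the center.

    Cropping is idempotent for an identical box and an empty site is
    permitted.
    """
    if not side_length > 0:
        raise ValidationError("side_length must be > 0")
    center = np.asarray(center, dtype=float)
    if center.shape != (locs.ndim,):
        raise ValidationError(
            f"center must have {locs.ndim} components, got {center.shape}")
    half = side_length / 2
    rel = locs.coords - center
    inside = (np.abs(rel) <= half).all(axis=1)
    cropped = locs.select(inside).with_coords(rel[inside])
    return Site(localizations=cropped, side_length=side_length,
                center=center, id=id)
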