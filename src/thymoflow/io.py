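"""Event-table container, file I/O and intensity transforms.

The :class:`EventTable` is the unit every gate operates on: an events x
channels matrix of non-negative fluorescence intensities plus channel
metadata and an explicit scale state (``raw`` or ``transformed``). Gating
runs on arcsinh-transformed intensities (``asinh(x / cofactor)``, default
cofactor 150 — a convention for conventional cytometers, not an instrument
value), while screen MFIs are always computed on the raw instrument scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, FormatError, PanelError, StateError
from . import _fcs

logger = logging.getLogger("thymoflow")

DEFAULT_COFACTOR = 150.0


@dataclass(frozen=True)
class ChannelMeta:
    """One cytometer channel: the marker it measures and (optionally) the detector."""

    marker: str
    detector: str = ""

    def __post_init__(self):
        if not self.marker:
            raise ConfigError("channel marker name must be non-empty")


@dataclass(frozen=True)
class TransformSpec:
    """Intensity transform: ``asinh(x / cofactor)``."""

    kind: str = "asinh"
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self):
        if self.kind != "asinh":
            raise ConfigError(f"unknown transform kind {self.kind!r}")
        if not self.cofactor > 0:
            raise ConfigError("transform cofactor must be > 0")

    def apply(self, values):
        # float32 inputs stay float32 (the simulator's dtype); ints promote
        return np.arcsinh(np.asarray(values) / self.cofactor)

    def invert(self, values):
        return np.sinh(np.asarray(values)) * self.cofactor


@dataclass(frozen=True)
class PanelConfig:
    """Required markers plus an alias map (alias -> canonical marker name)."""

    required_markers: tuple = ()
    marker_aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        # canonical names must not themselves be alias keys, so resolution
        # is idempotent by construction
        bad = set(self.marker_aliases) & set(self.marker_aliases.values())
        if bad:
            raise ConfigError(f"alias keys also appear as canonical names: {sorted(bad)}")

    def resolve(self, marker: str) -> str:
        return self.marker_aliases.get(marker, marker)

    def check(self, markers) -> None:
        resolved = {self.resolve(m) for m in markers}
        for req in self.required_markers:
            if req not in resolved:
                raise PanelError(f"required marker {req!r} not present in panel")


@dataclass
class EventTable:
    """Events x channels intensity matrix with marker metadata and scale state."""

    sample_id: str
    events: np.ndarray
    channels: list
    scale_state: str = "raw"
    transform: TransformSpec | None = None

    def __post_init__(self):
        self.events = np.asarray(self.events)
        if self.events.dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
            self.events = self.events.astype(np.float64)
        if self.events.ndim != 2:
            self.events = self.events.reshape(-1, len(self.channels))
        if self.events.shape[1] != len(self.channels):
            raise ConfigError("event matrix width does not match channel count")
        markers = [c.marker for c in self.channels]
        if len(set(markers)) != len(markers):
            raise ConfigError("channel marker names must be unique within a table")
        if (self.scale_state == "transformed") != (self.transform is not None):
            raise StateError("scale_state is 'transformed' iff a transform is set")
        if np.isnan(self.events).any():
            raise ConfigError("event matrix must not contain missing values")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def markers(self) -> list:
        return [c.marker for c in self.channels]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise PanelError(f"marker {marker!r} not present in table") from None

    def values(self, marker: str) -> np.ndarray:
        return self.events[:, self.marker_index(marker)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=self.markers)

    def copy(self) -> "EventTable":
        return EventTable(
            sample_id=self.sample_id,
            events=self.events.copy(),
            channels=list(self.channels),
            scale_state=self.scale_state,
            transform=self.transform,
        )


def _infer_format(path, fmt):
    if fmt is not None:
        return fmt
    s = str(path).lower()
    return "fcs" if s.endswith(".fcs") else "csv"


def read_events(path, format=None, panel: PanelConfig | None = None) -> EventTable:
    """Read a CSV (one-line marker header) or FCS 3.1 file into an EventTable.

    Marker names are resolved through the panel's aliases; missing required
    markers raise :class:`PanelError` naming the marker. Channels whose
    values are all negative are clipped at zero with a logged count.
    """
    fmt = _infer_format(path, format)
    transform = None
    scale_state = "raw"
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a parseable CSV file: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path}: CSV has no columns")
        markers = [str(c) for c in df.columns]
        detectors = [""] * len(markers)
        data = df.to_numpy(dtype=float)
        sample_id = str(path)
    elif fmt == "fcs":
        markers, detectors, data, kw = _fcs.read_fcs(path)
        sample_id = kw.get("SAMPLEID", str(path))
        if kw.get("TRANSFORM") == "asinh":
            transform = TransformSpec("asinh", float(kw.get("COFACTOR", DEFAULT_COFACTOR)))
            scale_state = "transformed"
    else:
        raise ConfigError(f"unknown format {fmt!r}")

    if panel is not None:
        markers = [panel.resolve(m) for m in markers]
        panel.check(markers)

    if data.size and scale_state == "raw":
        all_negative = (data < 0).all(axis=0)
        if all_negative.any():
            n_clipped = int((data[:, all_negative] < 0).sum())
            logger.warning(
                "clipped %d negative intensities at 0 in channels %s",
                n_clipped,
                [m for m, bad in zip(markers, all_negative) if bad],
            )
            data = np.where(data < 0, 0.0, data)

    channels = [ChannelMeta(m, d) for m, d in zip(markers, detectors)]
    return EventTable(sample_id, data, channels, scale_state, transform)


def write_events(table: EventTable, path, format=None):
    """Write an EventTable as CSV or FCS 3.1; re-readable by :func:`read_events`."""
    if len(table.channels) < 1:
        raise ConfigError("cannot write a table with no channels")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        table.to_dataframe().to_csv(path, index=False)
    elif fmt == "fcs":
        extra = {}
        if table.scale_state == "transformed":
            extra = {"TRANSFORM": table.transform.kind, "COFACTOR": table.transform.cofactor}
        _fcs.write_fcs(
            path,
            table.markers,
            table.events,
            detectors=[c.detector for c in table.channels],
            sample_id=table.sample_id,
            extra_keywords=extra,
        )
    else:
        raise ConfigError(f"unknown format {fmt!r}")
    return path


def transform_events(table: EventTable, spec: TransformSpec | None = None) -> EventTable:
    """Return a new table with ``asinh(x / cofactor)`` intensities.

    The input must be on the raw scale; the original table is unmodified.
    """
    if table.scale_state != "raw":
        raise StateError("table is already transformed")
    spec = spec or TransformSpec()
    return EventTable(
        sample_id=table.sample_id,
        events=spec.apply(table.events),
        channels=list(table.channels),
        scale_state="transformed",
        transform=spec,
    )


def untransform_events(table: EventTable) -> EventTable:
    """Invert the arcsinh transform, recovering raw-scale intensities."""
    if table.scale_state != "transformed":
        raise StateError("table is not transformed")
    return EventTable(
        sample_id=table.sample_id,
        events=table.transform.invert(table.events),
        channels=list(table.channels),
        scale_state="raw",
        transform=None,
    )


class ArcsinhTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying ``asinh(x / cofactor)``.

    Composes with sklearn pipelines; `inverse_transform` recovers the raw
    scale exactly (up to float round-off).
    """

    def __init__(self, cofactor: float = DEFAULT_COFACTOR):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if not self.cofactor > 0:
            raise ConfigError("transform cofactor must be > 0")
        self.n_features_in_ = np.asarray(X, dtype=float).shape[1] if np.ndim(X) == 2 else None
        return self

    def transform(self, X):
        return np.arcsinh(np.asarray(X, dtype=float) / self.cofactor)

    def inverse_transform(self, X):
        return np.sinh(np.asarray(X, dtype=float)) * self.cofactor


def load_panel_config(path) -> PanelConfig:
    """Load a PanelConfig from a YAML key-value file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PanelConfig(
        required_markers=tuple(doc.get("required_markers", ())),
        marker_aliases=dict(doc.get("marker_aliases", {})),
    )


def load_transform_spec(path) -> TransformSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return TransformSpec(
        kind=doc.get("kind", "asinh"),
        cofactor=float(doc.get("cofactor", DEFAULT_COFACTOR)),
    )
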