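"""Raster-format and binned-format data models, disk I/O, and temporal binning.

Neural recordings enter the pipeline in *raster-format*: one recording site
(a neuron, an LFP channel, an EEG sensor, ...) per file, holding a
trials x time-points activity matrix, per-trial condition labels, and
free-form site metadata.  Raster data is reduced to *binned-format* by
averaging activity over sliding time windows; all sites of a binned
collection share one bin specification and can therefore be stored together.

Time indices at the interface are 1-based and inclusive, so a window
described as (width=400, step=400, start=601, end=1000) covers raw columns
601..1000 of a 1000-point raster — exactly one bin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterator, Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger("popdecode")

BINNED_FORMAT_VERSION = 1

#: files in a raster bundle directory that are not site entries
_BUNDLE_PRIVATE_PREFIX = "_"


class FormatError(Exception):
    """A file on disk does not conform to the raster/binned layout."""


class ValidationError(ValueError):
    """In-memory data violates a format invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RasterSite:
    """One recording site: trials x time-points data plus per-trial labels.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_timepoints)``.  Binary 0/1 for spike
        rasters, arbitrary reals for continuous signals; no spike-specific
        assumption is made anywhere downstream.
    labels:
        Mapping from label-field name (e.g. ``"stimulus_ID"``) to a list of
        ``n_trials`` condition strings.  Label values are case-sensitive
        exact strings; no case folding is ever applied.
    site_info:
        Free-form scalar/string metadata (session, channel, brain area, ...).
    sampling_interval_ms:
        Duration of one raw time point in milliseconds (default 1).
    """

    data: np.ndarray
    labels: dict[str, list[str]]
    site_info: dict[str, Any] = field(default_factory=dict)
    sampling_interval_ms: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"raster data must be 2-D (trials x time points); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("raster data contains non-finite values")
        if self.sampling_interval_ms <= 0:
            raise ValidationError("sampling_interval_ms must be positive")
        self.labels = {k: [str(v) for v in vals] for k, vals in self.labels.items()}
        for name, values in self.labels.items():
            if len(values) != self.n_trials:
                raise ValidationError(
                    f"label {name!r} has {len(values)} entries for {self.n_trials} trials"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BinSpec:
    """Sliding-window averaging specification, 1-based inclusive indices.

    Bin ``b`` (1-based) covers raw columns
    ``start_index + (b-1)*step .. start_index + (b-1)*step + bin_width - 1``
    and bins are emitted while the window's last column is <= ``end_index``;
    a trailing window that would overrun ``end_index`` is dropped, never
    padded (a partial mean would change the estimator).
    """

    bin_width: int
    step: int
    start_index: int = 1
    end_index: int | None = None

    def resolve(self, n_timepoints: int) -> "BinSpec":
        """Return a copy with ``end_index`` defaulted to ``n_timepoints``."""
        end = self.end_index if self.end_index is not None else n_timepoints
        spec = BinSpec(self.bin_width, self.step, self.start_index, end)
        spec.validate(n_timepoints)
        return spec

    def validate(self, n_timepoints: int) -> None:
        if self.end_index is None:
            raise ValidationError("end_index is unresolved; call resolve() first")
        if self.bin_width < 1 or self.step < 1:
            raise ValidationError("bin_width and step must be >= 1")
        if not (1 <= self.start_index <= self.end_index <= n_timepoints):
            raise ValidationError(
                f"need 1 <= start_index ({self.start_index}) <= end_index "
                f"({self.end_index}) <= n_timepoints ({n_timepoints})"
            )
        if self.end_index - self.start_index + 1 < self.bin_width:
            raise ValidationError(
                f"window of {self.bin_width} points does not fit in "
                f"[{self.start_index}, {self.end_index}]"
            )

    @property
    def n_bins(self) -> int:
        assert self.end_index is not None
        span = self.end_index - self.start_index + 1
        return 1 + (span - self.bin_width) // self.step

    def windows(self) -> Iterator[tuple[int, int]]:
        """Yield (first, last) raw-column pairs, 1-based inclusive."""
        for b in range(self.n_bins):
            first = self.start_index + b * self.step
            yield first, first + self.bin_width - 1

    def bin_centers(self) -> np.ndarray:
        """Midpoint ``(first + last)/2`` of each window, in raw time-point units."""
        return np.array([(f + l) / 2.0 for f, l in self.windows()])


@dataclass
class BinnedCollection:
    """All sites of a dataset after temporal averaging.

    ``site_data[i]`` has shape ``(n_trials_i, n_bins)``; n_bins is identical
    across sites while trial counts may differ.  ``site_labels[i]`` carries
    the unmodified per-trial label lists of site ``i``.
    """

    site_data: list[np.ndarray]
    site_labels: list[dict[str, list[str]]]
    site_info: list[dict[str, Any]]
    bin_spec: BinSpec
    bin_centers: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.site_data) == len(self.site_labels) == len(self.site_info)):
            raise ValidationError("site_data, site_labels and site_info lengths differ")
        n_bins = {d.shape[1] for d in self.site_data}
        if len(n_bins) > 1:
            raise ValidationError(f"sites disagree on n_bins: {sorted(n_bins)}")
        for i, (data, labels) in enumerate(zip(self.site_data, self.site_labels)):
            for name, values in labels.items():
                if len(values) != data.shape[0]:
                    raise ValidationError(
                        f"site {i}: label {name!r} has {len(values)} entries "
                        f"for {data.shape[0]} trials"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.site_data)

    @property
    def n_bins(self) -> int:
        return int(self.site_data[0].shape[1]) if self.site_data else 0

    @property
    def label_names(self) -> list[str]:
        return sorted(self.site_labels[0].keys()) if self.site_labels else []


# ---------------------------------------------------------------------------
# Raster bundle I/O
# ---------------------------------------------------------------------------
# On-disk layout: one <stem>.npy (dense float matrix) + <stem>.json sidecar
# per site.  The sidecar holds labels, site_info and the sampling interval so
# that the condition structure stays human-inspectable.


def write_raster_bundle(sites: Sequence[RasterSite], path: str | Path) -> Path:
    """Write sites to ``path`` (a directory), one .npy/.json pair per site.

    Site files are named ``site_0000`` onward in list order, so a subsequent
    :func:`read_raster_bundle` (lexicographic order) reproduces the list.
    """
    if len(sites) == 0:
        raise ValueError("cannot write an empty raster bundle")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(sites) - 1)))
    for i, site in enumerate(sites):
        stem = path / f"site_{i:0{width}d}"
        np.save(stem.with_suffix(".npy"), site.data)
        sidecar = {
            "labels": site.labels,
            "site_info": site.site_info,
            "sampling_interval_ms": site.sampling_interval_ms,
        }
        stem.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )
    return path


def read_raster_bundle(path: str | Path) -> list[RasterSite]:
    """Read all site files from a raster bundle directory.

    Sites are returned in lexicographic order of their file names.  Files
    whose names start with ``_`` (e.g. a generator-config sidecar) are not
    site entries and are skipped.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"raster bundle directory not found: {path}")
    stems = sorted(
        p.with_suffix("")
        for p in path.iterdir()
        if p.suffix == ".npy" and not p.name.startswith(_BUNDLE_PRIVATE_PREFIX)
    )
    if not stems:
        raise FormatError(f"no site files (*.npy) in raster bundle {path}")
    sites = []
    for stem in stems:
        sidecar_path = stem.with_suffix(".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing label sidecar for site file {stem.name}.npy")
        try:
            sidecar = json.loads(sidecar_path.read_text())
            data = np.load(stem.with_suffix(".npy"))
        except (json.JSONDecodeError, ValueError, OSError) as exc:
            raise FormatError(f"malformed site file {stem.name}: {exc}") from exc
        try:
            site = RasterSite(
                data=data,
                labels=sidecar["labels"],
                site_info=sidecar.get("site_info", {}),
                sampling_interval_ms=sidecar.get("sampling_interval_ms", 1.0),
            )
        except KeyError as exc:
            raise FormatError(f"site {stem.name}: sidecar missing key {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"site {stem.name}: {exc}") from exc
        sites.append(site)
    return sites


def export_site_csv(site: RasterSite, path: str | Path) -> Path:
    """Dump one site's data matrix as CSV for eyeball inspection."""
    path = Path(path)
    np.savetxt(path, site.data, delimiter=",", fmt="%.17g")
    return path


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_one_site(data: np.ndarray, spec: BinSpec) -> np.ndarray:
    """Average one site's trials x time-points matrix over sliding windows.

    Returns a trials x n_bins matrix; entry ``[i, b]`` is the arithmetic
    mean of the raw columns covered by window ``b``.  For a binary spike
    raster this is spike count in window / bin_width, i.e. firing rate in
    spikes per time point.
    """
    data = np.asarray(data, dtype=float)
    spec = spec.resolve(data.shape[1])
    cols = []
    for first, last in spec.windows():
        cols.append(data[:, first - 1 : last].mean(axis=1))
    return np.column_stack(cols)


def bin_sites(sites: Sequence[RasterSite], spec: BinSpec) -> BinnedCollection:
    """Bin an in-memory list of raster sites into one collection.

    All sites must share ``n_timepoints``; the spec is resolved against it.
    """
    if not sites:
        raise ValueError("no sites to bin")
    n_timepoints = {s.n_timepoints for s in sites}
    if len(n_timepoints) > 1:
        offenders = [
            i for i, s in enumerate(sites) if s.n_timepoints != sites[0].n_timepoints
        ]
        raise ValidationError(
            f"sites disagree on n_timepoints {sorted(n_timepoints)}; "
            f"offending site indices (vs site 0): {offenders}"
        )
    spec = spec.resolve(sites[0].n_timepoints)
    return BinnedCollection(
        site_data=[bin_one_site(s.data, spec) for s in sites],
        site_labels=[s.labels for s in sites],
        site_info=[s.site_info for s in sites],
        bin_spec=spec,
        bin_centers=spec.bin_centers(),
    )


def create_binned_data(
    raster_dir: str | Path,
    bin_width: int,
    step: int,
    start_index: int = 1,
    end_index: int | None = None,
    save_path: str | Path | None = None,
) -> tuple[BinnedCollection, Path]:
    """Convert a raster bundle into a binned collection and persist it.

    All sites must share one ``n_timepoints``.  The collection is saved as a
    single HDF5 container (``save_path``; default
    ``<raster_dir>_binned_<bin_width>_<step>.h5``) and returned together with
    the saved file's path.
    """
    raster_dir = Path(raster_dir)
    sites = read_raster_bundle(raster_dir)
    collection = bin_sites(sites, BinSpec(bin_width, step, start_index, end_index))
    if save_path is None:
        save_path = raster_dir.parent / f"{raster_dir.name}_binned_{bin_width}_{step}.h5"
    save_binned(collection, save_path)
    return collection, Path(save_path)


# ---------------------------------------------------------------------------
# Binned-format container
# ---------------------------------------------------------------------------


def save_binned(collection: BinnedCollection, path: str | Path) -> Path:
    """Save a binned collection as a single HDF5 file.

    Per-site matrices go into ``sites/<i>/data``; labels and site_info are
    stored as JSON strings so arbitrary string labels survive untouched.
    Datasets are written with ``track_times=False`` so identical collections
    produce byte-identical files.
    """
    path = Path(path)
    spec = collection.bin_spec
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = BINNED_FORMAT_VERSION
        f.attrs["n_sites"] = collection.n_sites
        f.attrs["bin_width"] = spec.bin_width
        f.attrs["step"] = spec.step
        f.attrs["start_index"] = spec.start_index
        f.attrs["end_index"] = spec.end_index
        f.create_dataset("bin_centers", data=collection.bin_centers, track_times=False)
        grp = f.create_group("sites")
        for i in range(collection.n_sites):
            g = grp.create_group(str(i))
            g.create_dataset("data", data=collection.site_data[i], track_times=False)
            g.create_dataset(
                "labels",
                data=json.dumps(collection.site_labels[i], sort_keys=True),
                track_times=False,
            )
            g.create_dataset(
                "site_info",
                data=json.dumps(collection.site_info[i], sort_keys=True),
                track_times=False,
            )
    return path


def load_binned(path: str | Path) -> BinnedCollection:
    """Load a binned collection saved by :func:`save_binned`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"binned file not found: {path}")
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != BINNED_FORMAT_VERSION:
            raise FormatError(
                f"binned file {path} has format version {version}; "
                f"expected {BINNED_FORMAT_VERSION}"
            )
        spec = BinSpec(
            int(f.attrs["bin_width"]),
            int(f.attrs["step"]),
            int(f.attrs["start_index"]),
            int(f.attrs["end_index"]),
        )
        n_sites = int(f.attrs["n_sites"])
        site_data, site_labels, site_info = [], [], []
        for i in range(n_sites):
            g = f[f"sites/{i}"]
            site_data.append(np.asarray(g["data"]))
            site_labels.append(json.loads(g["labels"][()].decode()))
            site_info.append(json.loads(g["site_info"][()].decode()))
        centers = np.asarray(f["bin_centers"])
    return BinnedCollection(site_data, site_labels, site_info, spec, centers)
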