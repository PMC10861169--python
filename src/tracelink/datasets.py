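"""Input data model: tract-tracing matrices, atlases, and the weight/distance transforms.

Retrograde tract-tracing reveals, for each injected *target* area, the full set
of *source* areas projecting into it, with connection strength recorded as the
fraction of labeled neurons (FLN).  The observed data is therefore a row
submatrix G(T x N) of the full interareal network G(N x N): row i = injected
target, column j = source, entry FLN_ij in [0, 1].

Two preprocessing transforms put the data on the scales the predictors use:

* weights      w_ij = 7 + log10(FLN_ij)   (nonlinks stay exactly 0),
  mapping the ~1e-7..1 FLN range onto ~0..7;
* distances    dfeat_ij = 31 * D_ij / Dmax, mapping barycenter distances in mm
  onto 0..31.

Weight classes partition links by strength with deliberately inclusive
boundaries: strong (w >= 5), strong_medium (w >= 3), medium_weak (0 < w <= 5),
weak (0 < w <= 3).  The nonlink cutoff ``W_CUT = 0.9`` corresponds to the
lowest statistically acceptable FLN of 8e-7 and is used as the surrogate
ground-truth weight when relative errors are computed for nonlinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDistances,
    LowWeightWarning,
    MissingArea,
    MissingRegion,
    ShapeMismatch,
    ValueOutOfRange,
)

#: lowest statistically acceptable weight; FLN = 8e-7 -> w = 7 + log10(8e-7) ~ 0.9
W_CUT: float = 0.9

#: scaling constant for the distance feature (max scaled distance)
DISTANCE_FEATURE_MAX: float = 31.0

#: relative tolerance when validating symmetry of the distance matrix
SYMMETRY_RTOL: float = 1e-6

WEIGHT_CLASSES = ("strong", "strong_medium", "medium_weak", "weak")


@dataclass(frozen=True)
class AreaAtlas:
    """Ordered area names, region (lobe) assignments, and the injected subset."""

    area_names: tuple[str, ...]
    region_of: dict[str, str]
    injected: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.area_names)) != len(self.area_names):
            dupes = [a for a in self.area_names if list(self.area_names).count(a) > 1]
            raise ValueOutOfRange(f"duplicate area names: {sorted(set(dupes))}")
        for a in self.injected:
            if a not in self.area_names:
                raise MissingArea(f"injected area {a!r} not in atlas")
        if len(set(self.injected)) != len(self.injected):
            raise ValueOutOfRange("duplicate injected areas")
        for a in self.area_names:
            region = self.region_of.get(a)
            if not region:
                raise MissingRegion(f"area {a!r} has no region label")

    @property
    def n_areas(self) -> int:
        return len(self.area_names)

    @property
    def n_injected(self) -> int:
        return len(self.injected)

    def index_of(self, area: str) -> int:
        try:
            return self.area_names.index(area)
        except ValueError:
            raise MissingArea(f"unknown area {area!r}") from None

    @property
    def injected_indices(self) -> np.ndarray:
        """Global indices of injected areas, in injection (row) order."""
        return np.array([self.index_of(a) for a in self.injected], dtype=int)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.area_names:
            seen.setdefault(self.region_of[a], None)
        return tuple(seen)


@dataclass(frozen=True)
class TracingDataset:
    """A partial observation of a weighted directed interareal network.

    ``fln[i, j]`` is the FLN from source ``atlas.area_names[j]`` into injected
    target ``atlas.injected[i]``; ``dist`` is the full symmetric N x N
    barycenter distance matrix in mm, ordered like ``atlas.area_names``.
    """

    fln: np.ndarray
    dist: np.ndarray
    atlas: AreaAtlas

    def __post_init__(self) -> None:
        fln = np.asarray(self.fln, dtype=float)
        dist = np.asarray(self.dist, dtype=float)
        object.__setattr__(self, "fln", fln)
        object.__setattr__(self, "dist", dist)
        T, N = self.atlas.n_injected, self.atlas.n_areas
        if fln.shape != (T, N):
            raise ShapeMismatch(f"fln shape {fln.shape} != (T={T}, N={N})")
        if dist.shape != (N, N):
            raise ShapeMismatch(f"dist shape {dist.shape} != ({N}, {N})")
        bad = np.argwhere((fln < 0) | (fln > 1) | ~np.isfinite(fln))
        if bad.size:
            i, j = bad[0]
            raise ValueOutOfRange(
                f"FLN[{self.atlas.injected[i]!r}, {self.atlas.area_names[j]!r}]"
                f" = {fln[i, j]} outside [0, 1]"
            )
        rows = self.atlas.injected_indices
        diag = fln[np.arange(T), rows]
        if np.any(diag != 0):
            k = int(np.argmax(diag != 0))
            raise ValueOutOfRange(f"self-link FLN for {self.atlas.injected[k]!r} nonzero")
        if np.any(dist < 0):
            i, j = np.argwhere(dist < 0)[0]
            raise ValueOutOfRange(
                f"negative distance at ({self.atlas.area_names[i]!r},"
                f" {self.atlas.area_names[j]!r})"
            )
        if np.any(np.diag(dist) != 0):
            k = int(np.argmax(np.diag(dist) != 0))
            raise ValueOutOfRange(f"nonzero diagonal distance for {self.atlas.area_names[k]!r}")
        scale = max(dist.max(), 1.0)
        if not np.allclose(dist, dist.T, rtol=0, atol=SYMMETRY_RTOL * scale):
            i, j = np.argwhere(~np.isclose(dist, dist.T, rtol=0, atol=SYMMETRY_RTOL * scale))[0]
            raise ValueOutOfRange(
                f"dist asymmetric at ({self.atlas.area_names[i]!r},"
                f" {self.atlas.area_names[j]!r})"
            )

    @property
    def n_injected(self) -> int:
        return self.atlas.n_injected

    @property
    def n_areas(self) -> int:
        return self.atlas.n_areas

    @property
    def dmax(self) -> float:
        return float(self.dist.max())

    @property
    def density(self) -> float:
        """Binary density of the observed view (self-pairs excluded)."""
        T, N = self.fln.shape
        return float((self.fln > 0).sum()) / (T * (N - 1))


@dataclass(frozen=True)
class WeightMatrix:
    """Log-transformed weights on the ~0-7 scale; 0 encodes a nonlink."""

    w: np.ndarray
    atlas: AreaAtlas

    @property
    def links(self) -> np.ndarray:
        """Boolean mask of existing links in the observed T x N view."""
        return self.w > 0

    @property
    def binary(self) -> np.ndarray:
        return (self.w > 0).astype(int)


@dataclass(frozen=True)
class DistanceFeatures:
    """Distances rescaled to the 0-31 feature range; dmax retains the mm scale."""

    dfeat: np.ndarray
    dmax: float


@dataclass(frozen=True)
class WeightClassSpec:
    """Inclusive weight-class thresholds over transformed weights.

    Boundary weights belong to both adjacent classes by construction
    (w = 5.0 is both strong and medium_weak; w = 3.0 is strong_medium,
    medium_weak and weak).
    """

    strong_min: float = 5.0
    medium_min: float = 3.0
    w_cut: float = W_CUT
    class_ids: tuple[str, ...] = field(default=WEIGHT_CLASSES)

    def mask(self, class_id: str, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        link = w > 0
        if class_id == "strong":
            return link & (w >= self.strong_min)
        if class_id == "strong_medium":
            return link & (w >= self.medium_min)
        if class_id == "medium_weak":
            return link & (w <= self.strong_min)
        if class_id == "weak":
            return link & (w <= self.medium_min)
        raise KeyError(f"unknown weight class {class_id!r}")


def transform_weights(ds: TracingDataset) -> WeightMatrix:
    """Map FLN onto the ~0-7 log scale: w = 7 + log10(FLN), zeros left as zeros.

    FLN below 1e-7 yields w < 0; such entries are retained but flagged with a
    :class:`~tracelink.errors.LowWeightWarning` (the 0-7 range is empirical,
    not enforced).
    """
    fln = ds.fln
    w = np.zeros_like(fln)
    nz = fln > 0
    w[nz] = 7.0 + np.log10(fln[nz])
    if np.any(w[nz] < 0):
        warnings.warn(
            f"{int((w[nz] < 0).sum())} FLN entries below 1e-7 map to negative weights",
            LowWeightWarning,
            stacklevel=2,
        )
    return WeightMatrix(w=w, atlas=ds.atlas)


def inverse_transform_weights(w: np.ndarray) -> np.ndarray:
    """Invert the weight transform: FLN = 10^(w - 7) for links, 0 for nonlinks."""
    w = np.asarray(w, dtype=float)
    fln = np.zeros_like(w)
    nz = w > 0
    fln[nz] = 10.0 ** (w[nz] - 7.0)
    return fln


def dataset_from_weights(wm: WeightMatrix, dist: np.ndarray) -> TracingDataset:
    """Rebuild a TracingDataset from a (possibly rewired/perturbed) weight
    matrix by inverting the weight transform."""
    return TracingDataset(fln=inverse_transform_weights(wm.w), dist=np.asarray(dist, float),
                         atlas=wm.atlas)


def scale_distances(ds: TracingDataset) -> DistanceFeatures:
    """Rescale barycenter distances to the 0-31 feature range (max maps to 31)."""
    dmax = ds.dmax
    if dmax <= 0:
        raise DegenerateDistances("all distances are zero")
    return DistanceFeatures(dfeat=DISTANCE_FEATURE_MAX * ds.dist / dmax, dmax=dmax)


def assign_weight_classes(
    wm: WeightMatrix, spec: WeightClassSpec | None = None
) -> dict[str, np.ndarray]:
    """Boolean membership mask per weight class; masks cover links only."""
    spec = spec or WeightClassSpec()
    return {cid: spec.mask(cid, wm.w) for cid in spec.class_ids}


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma-separated UTF-8; first row and first column carry area names;
# floats written with repr() so a write/load round trip is bit-identical.


def _write_matrix(path: Path, values: np.ndarray, row_names, col_names) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("," + ",".join(col_names) + "\n")
        for name, row in zip(row_names, values):
            fh.write(name + "," + ",".join(repr(float(x)) for x in row) + "\n")


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, index_col=0, header=0, encoding="utf-8",
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def load_tracing_dataset(fln_path, dist_path, atlas_path) -> TracingDataset:
    """Load and validate a tracing dataset from three CSV files.

    ``fln_path``: T x N matrix, row names = injected targets, column names =
    all areas.  ``dist_path``: N x N symmetric matrix.  ``atlas_path``: rows
    ``area,region``; row order defines the global area order.  Injection order
    is taken from the FLN row order.
    """
    fln, fln_rows, fln_cols = _read_matrix(Path(fln_path))
    dist, dist_rows, dist_cols = _read_matrix(Path(dist_path))
    adf = pd.read_csv(atlas_path, encoding="utf-8")
    if not {"area", "region"} <= set(adf.columns):
        raise MissingRegion(f"atlas file {atlas_path} must have 'area' and 'region' columns")
    area_names = tuple(str(a) for a in adf["area"])
    region_of = {str(a): str(r) for a, r in zip(adf["area"], adf["region"])}

    if list(area_names) != fln_cols:
        extra = set(fln_cols) - set(area_names)
        missing = set(area_names) - set(fln_cols)
        if extra or missing:
            raise MissingArea(f"FLN columns disagree with atlas (extra={extra}, missing={missing})")
        raise ShapeMismatch("FLN column order differs from atlas area order")
    if dist_rows != list(area_names) or dist_cols != list(area_names):
        raise ShapeMismatch("distance matrix row/column names must match atlas area order")
    for t in fln_rows:
        if t not in area_names:
            raise MissingArea(f"injected target {t!r} not in atlas")

    atlas = AreaAtlas(area_names=area_names, region_of=region_of, injected=tuple(fln_rows))
    return TracingDataset(fln=fln, dist=dist, atlas=atlas)


def save_tracing_dataset(ds: TracingDataset, fln_path, dist_path, atlas_path) -> None:
    """Write the three CSV files of :func:`load_tracing_dataset` (round-trip safe)."""
    _write_matrix(Path(fln_path), ds.fln, ds.atlas.injected, ds.atlas.area_names)
    _write_matrix(Path(dist_path), ds.dist, ds.atlas.area_names, ds.atlas.area_names)
    with open(atlas_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("area,region,injected\n")
        injected = set(ds.atlas.injected)
        for a in ds.atlas.area_names:
            fh.write(f"{a},{ds.atlas.region_of[a]},{int(a in injected)}\n")
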