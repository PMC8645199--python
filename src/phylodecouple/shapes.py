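"""Landmark I/O and geometric morphometrics.

Generalized Procrustes analysis (GPA), bilateral mirroring of a
half-configuration, subset extraction without re-alignment, species mean
shapes, Procrustes distances, shape PCA, and metric trait extraction.

Two datasets flow through here: a 2-D premaxilla (four landmarks taken
out of a whole-body configuration *after* full-body superimposition, so
its relative size and orientation with respect to the body axes are
retained) and a 3-D lower-pharyngeal-jaw configuration obtained by
mirroring digitized left-side landmarks across the best-fit symmetry
plane.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "AlignedDataset",
    "SpeciesMeanShape",
    "ShapePCA",
    "gpa",
    "mirror_landmarks",
    "extract_recentered_subset",
    "mean_shape",
    "species_mean_shapes",
    "procrustes_distance",
    "shape_pca",
    "metric_traits",
    "centroid_size",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
]

STRUCTURES = {"oral_full_skeleton", "oral_premaxilla", "lpj_half", "lpj_full"}


@dataclass
class LandmarkConfiguration:
    """Raw landmark coordinates of one structure for one specimen."""

    specimen_id: str
    species_id: str
    structure: str
    coords: np.ndarray  # (K, dims)

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be K x 2 or K x 3")
        if not np.isfinite(self.coords).all():
            raise ValueError(
                f"missing/non-finite coordinates in specimen {self.specimen_id}"
            )

    @property
    def dims(self) -> int:
        return self.coords.shape[1]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class AlignedDataset:
    configurations: list[LandmarkConfiguration]
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    scaled: bool
    n_iterations: int


@dataclass(frozen=True)
class SpeciesMeanShape:
    species_id: str
    coords: np.ndarray


@dataclass(frozen=True)
class ShapePCA:
    species_ids: tuple[str, ...]
    scores: np.ndarray            # species x axes
    percent_variance: np.ndarray  # per axis, sums to 100
    loadings: np.ndarray          # flattened-coordinate loadings per axis
    mean: np.ndarray              # flattened consensus of species means

    def axis_deformations(self, axis: int, magnitude: float | None = None):
        """Mean shape deformed to the ± extreme of one axis."""
        if magnitude is None:
            magnitude = float(np.abs(self.scores[:, axis]).max())
        lo = self.mean - magnitude * self.loadings[:, axis]
        hi = self.mean + magnitude * self.loadings[:, axis]
        return lo, hi


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances from the centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation of centered ``moving`` onto centered ``target``."""
    H = moving.T @ target
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def gpa(
    configs: list[LandmarkConfiguration],
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes superimposition.

    Removes translation (centroids to the origin), optionally scale
    (unit centroid size), and rotation (minimizing summed squared
    distance to the iteratively updated consensus). Reflections are not
    allowed — rotations are proper.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k, d = configs[0].coords.shape
    for c in configs:
        if c.coords.shape != (k, d):
            raise ValueError(
                f"specimen {c.specimen_id}: landmark count/dims mismatch"
            )
    sizes = np.empty(len(configs))
    arr = np.empty((len(configs), k, d))
    for i, c in enumerate(configs):
        x = c.coords - c.coords.mean(axis=0)
        s = np.sqrt((x**2).sum())
        if s < 1e-300:
            raise ValueError(
                f"degenerate configuration (all landmarks coincide): "
                f"specimen {c.specimen_id}"
            )
        sizes[i] = s
        arr[i] = x / s if scale else x
    consensus = arr[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(len(configs)):
            arr[i] = arr[i] @ _optimal_rotation(arr[i], consensus)
        new_consensus = arr.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = np.abs(new_consensus - consensus).max()
        consensus = new_consensus
        if change < tol:
            break
    consensus = arr.mean(axis=0)
    # canonical orientation: principal axes of the consensus with a
    # largest-coordinate-positive sign rule, so the aligned dataset is
    # invariant to any common rigid motion of the inputs
    R = _canonical_rotation(consensus)
    consensus = consensus @ R
    for i in range(len(configs)):
        arr[i] = arr[i] @ R
    aligned = [
        LandmarkConfiguration(c.specimen_id, c.species_id, c.structure, arr[i])
        for i, c in enumerate(configs)
    ]
    return AlignedDataset(aligned, sizes, consensus, scale, n_iter)


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to its principal axes."""
    d = consensus.shape[1]
    _, _, Vt = np.linalg.svd(consensus - consensus.mean(axis=0))
    R = Vt.T
    if np.linalg.det(R) < 0:
        R[:, -1] *= -1.0
    rotated = consensus @ R
    for j in range(d - 1):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            R[:, j] *= -1.0
            R[:, -1] *= -1.0  # keep det = +1
            rotated = consensus @ R
    return R


def mirror_landmarks(
    config: LandmarkConfiguration,
    midline_ids: np.ndarray | list[int],
    paired_ids: np.ndarray | list[int],
) -> LandmarkConfiguration:
    """Mirror paired landmarks across the best-fit bilateral symmetry plane.

    The plane is the least-squares plane through the midline landmarks;
    midline landmarks are projected onto it, paired landmarks are
    reflected, and the output stacks midline + paired + mirrored copies
    (K -> |midline| + 2 |paired|).
    """
    midline_ids = np.asarray(midline_ids, dtype=int)
    paired_ids = np.asarray(paired_ids, dtype=int)
    if config.dims != 3:
        raise ValueError("mirroring requires 3-D landmarks")
    k = config.n_landmarks
    if sorted(np.concatenate([midline_ids, paired_ids]).tolist()) != list(range(k)):
        raise ValueError("midline_ids + paired_ids must partition the landmarks")
    mid = config.coords[midline_ids]
    center = mid.mean(axis=0)
    _, s, Vt = np.linalg.svd(mid - center)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("midline landmarks are collinear; symmetry plane undefined")
    normal = Vt[2]
    def reflect(p):
        return p - 2.0 * ((p - center) @ normal)[:, None] * normal
    mid_proj = mid - ((mid - center) @ normal)[:, None] * normal
    paired = config.coords[paired_ids]
    mirrored = reflect(paired)
    coords = np.vstack([mid_proj, paired, mirrored])
    return LandmarkConfiguration(
        config.specimen_id, config.species_id, "lpj_full", coords
    )


def extract_recentered_subset(
    aligned: AlignedDataset, subset_ids: list[int] | np.ndarray
) -> list[LandmarkConfiguration]:
    """Premaxilla extraction: subset of an aligned dataset, re-centered only.

    Coordinates are taken verbatim from the whole-body alignment and
    translated so the subset centroid sits at the origin; no re-rotation
    and no re-scaling, so relative size and orientation with respect to
    the body are preserved.
    """
    subset_ids = np.asarray(subset_ids, dtype=int)
    if subset_ids.size != 4:
        raise ValueError("premaxilla subset must name exactly 4 landmarks")
    k = aligned.configurations[0].n_landmarks
    if subset_ids.min() < 0 or subset_ids.max() >= k:
        raise ValueError("subset landmark index out of range")
    out = []
    for c in aligned.configurations:
        sub = c.coords[subset_ids]
        sub = sub - sub.mean(axis=0)
        out.append(
            LandmarkConfiguration(
                c.specimen_id, c.species_id, "oral_premaxilla", sub
            )
        )
    return out


def mean_shape(configs: list[LandmarkConfiguration]) -> SpeciesMeanShape:
    """Coordinate-wise arithmetic mean of one species' aligned specimens."""
    if not configs:
        raise ValueError("cannot average an empty set of configurations")
    species = {c.species_id for c in configs}
    if len(species) != 1:
        raise ValueError(f"configurations from multiple species: {sorted(species)}")
    coords = np.mean([c.coords for c in configs], axis=0)
    return SpeciesMeanShape(configs[0].species_id, coords)


def species_mean_shapes(
    aligned: AlignedDataset | list[LandmarkConfiguration],
) -> list[SpeciesMeanShape]:
    """Mean shape per species, ordered by species id."""
    configs = (
        aligned.configurations if isinstance(aligned, AlignedDataset) else aligned
    )
    by_species: dict[str, list[LandmarkConfiguration]] = {}
    for c in configs:
        by_species.setdefault(c.species_id, []).append(c)
    return [mean_shape(by_species[s]) for s in sorted(by_species)]


def procrustes_distance(
    a: SpeciesMeanShape | np.ndarray,
    b: SpeciesMeanShape | np.ndarray,
    scale: bool = True,
) -> float:
    """Root summed squared difference after superimposing ``b`` onto ``a``.

    Translation and proper rotation are always removed; with
    ``scale=True`` both configurations are first scaled to unit centroid
    size (matching a size-removing alignment upstream).
    """
    xa = a.coords if isinstance(a, SpeciesMeanShape) else np.asarray(a, float)
    xb = b.coords if isinstance(b, SpeciesMeanShape) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise ValueError("configurations differ in landmarks/dims")
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    if scale:
        xa = xa / np.sqrt((xa**2).sum())
        xb = xb / np.sqrt((xb**2).sum())
    xb = xb @ _optimal_rotation(xb, xa)
    return float(np.sqrt(((xa - xb) ** 2).sum()))


def shape_pca(means: list[SpeciesMeanShape]) -> ShapePCA:
    """PCA of flattened species mean coordinates.

    Axis signs follow the largest-magnitude-loading-positive convention
    so orientations are reproducible.
    """
    if len(means) < 3:
        raise ValueError("shape PCA needs at least 3 species")
    ids = tuple(m.species_id for m in means)
    X = np.array([m.coords.ravel() for m in means])
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_axes = int((s > s[0] * 1e-12).sum()) if s[0] > 0 else 0
    if n_axes == 0:
        raise ValueError("species means are all identical; PCA undefined")
    s = s[:n_axes]
    V = Vt[:n_axes].T
    scores = Xc @ V
    for j in range(n_axes):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] *= -1.0
            scores[:, j] *= -1.0
    var = s**2
    pct = 100.0 * var / var.sum()
    return ShapePCA(ids, scores, pct, V, mu)


# -- metric traits ---------------------------------------------------------


def _angle(coords: np.ndarray, trio_or_vectors) -> float:
    """Angle in degrees between two landmark-defined vectors."""
    if len(trio_or_vectors) == 3:
        a, b, c = trio_or_vectors
        v1 = coords[a] - coords[b]
        v2 = coords[c] - coords[b]
    else:
        (a, b), (c, d) = trio_or_vectors
        v1 = coords[b] - coords[a]
        v2 = coords[d] - coords[c]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-300 or n2 < 1e-300:
        raise ValueError("coincident landmarks define a zero-length vector")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dist(coords: np.ndarray, pair) -> float:
    a, b = pair
    d = float(np.linalg.norm(coords[a] - coords[b]))
    if d < 1e-300:
        raise ValueError("coincident landmarks give a zero distance")
    return d


def _polygon_area(coords: np.ndarray, ring) -> float:
    pts = coords[list(ring)]
    if pts.shape[1] == 2:
        x, y = pts[:, 0], pts[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    # 3-D planar polygon: fan triangulation cross-product area
    total = np.zeros(3)
    for i in range(1, len(pts) - 1):
        total += np.cross(pts[i] - pts[0], pts[i + 1] - pts[0])
    return float(0.5 * np.linalg.norm(total))


def metric_traits(
    config: LandmarkConfiguration, spec: dict[str, dict]
) -> dict[str, float]:
    """Named metric traits from a landmark configuration.

    Each trait definition is a dict with a ``kind`` key:

    - ``angle``: ``landmarks`` = (a, b, c) vertex trio or two (start, end)
      pairs; degrees in [0, 180].
    - ``distance_ratio``: ``numerator``/``denominator`` landmark pairs.
    - ``distance_over_centroid_size``: ``landmarks`` pair.
    - ``area_ratio``: ``numerator``/``denominator`` polygon rings.
    """
    coords = config.coords
    out: dict[str, float] = {}
    for name, d in spec.items():
        kind = d["kind"]
        if kind == "angle":
            out[name] = _angle(coords, d["landmarks"])
        elif kind == "distance_ratio":
            out[name] = _dist(coords, d["numerator"]) / _dist(
                coords, d["denominator"]
            )
        elif kind == "distance_over_centroid_size":
            out[name] = _dist(coords, d["landmarks"]) / centroid_size(coords)
        elif kind == "area_ratio":
            num = _polygon_area(coords, d["numerator"])
            den = _polygon_area(coords, d["denominator"])
            if den <= 0:
                raise ValueError(f"trait {name!r}: zero denominator area")
            out[name] = num / den
        else:
            raise ValueError(f"trait {name!r}: unknown kind {kind!r}")
    return out


# -- file formats ----------------------------------------------------------


def read_tps(
    text: str, structure: str, species_map: dict[str, str] | None = None
) -> list[LandmarkConfiguration]:
    """Parse TPS records (LM=/LM3= blocks with ID= keys).

    ``species_map`` maps specimen id to species id; without it, the
    species id defaults to the specimen id up to the last underscore.
    """
    configs = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        ln = lines[i]
        up = ln.upper()
        if not (up.startswith("LM=") or up.startswith("LM3=")):
            raise ValueError(f"expected LM=/LM3= record, got {ln!r}")
        k = int(ln.split("=", 1)[1])
        i += 1
        pts = []
        for _ in range(k):
            pts.append([float(v) for v in lines[i].split()])
            i += 1
        spec_id = None
        while i < len(lines) and not lines[i].upper().startswith(("LM=", "LM3=")):
            if lines[i].upper().startswith("ID="):
                spec_id = lines[i].split("=", 1)[1]
            i += 1
        if spec_id is None:
            spec_id = f"specimen{len(configs) + 1}"
        species = (
            species_map.get(spec_id) if species_map else spec_id.rsplit("_", 1)[0]
        )
        if species is None:
            raise ValueError(f"specimen {spec_id!r} missing from species map")
        configs.append(
            LandmarkConfiguration(spec_id, species, structure, np.array(pts))
        )
    return configs


def write_tps(configs: list[LandmarkConfiguration]) -> str:
    buf = io.StringIO()
    for c in configs:
        tag = "LM" if c.dims == 2 else "LM3"
        buf.write(f"{tag}={c.n_landmarks}\n")
        for row in c.coords:
            buf.write(" ".join(f"{v:.10g}" for v in row) + "\n")
        buf.write(f"ID={c.specimen_id}\n")
    return buf.getvalue()


def read_landmark_csv(source, structure: str) -> list[LandmarkConfiguration]:
    """Long-format CSV: specimen_id, species_id, landmark_index, x, y[, z]."""
    df = pd.read_csv(source)
    required = {"specimen_id", "species_id", "landmark_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV needs columns {sorted(required)}")
    dims = 3 if "z" in df.columns else 2
    cols = ["x", "y", "z"][:dims]
    configs = []
    for (spec_id, species), g in df.groupby(
        ["specimen_id", "species_id"], sort=True
    ):
        g = g.sort_values("landmark_index")
        configs.append(
            LandmarkConfiguration(
                str(spec_id), str(species), structure, g[cols].to_numpy()
            )
        )
    return configs


def write_landmark_csv(configs: list[LandmarkConfiguration]) -> str:
    rows = []
    for c in configs:
        for idx, pt in enumerate(c.coords):
            row = {
                "specimen_id": c.specimen_id,
                "species_id": c.species_id,
                "landmark_index": idx,
                "x": pt[0],
                "y": pt[1],
            }
            if c.dims == 3:
                row["z"] = pt[2]
            rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False)
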