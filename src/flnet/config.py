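"""Configuration objects shared across the pipeline.

Three families of settings live here:

* :class:`TaskParadigm` — timing of the block-design task (epochs of task
  followed by rest, sampled every TR seconds).
* :class:`AnalysisConfig` — every tunable of the analysis chain, from the
  voxel-wise significance threshold down to the number of occupancy bins.
* :class:`RegionSpec` / :class:`SyntheticConfig` — the generative model for
  synthetic multi-subject BOLD data with planted active regions and a
  controllable inter-region coupling structure.

All configs validate themselves on construction and round-trip losslessly
through JSON (``to_json`` / ``from_json``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TaskParadigm",
    "AnalysisConfig",
    "RegionSpec",
    "SyntheticConfig",
    "pair_key",
]


class ValidationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered region pair."""
    if a == b:
        raise ValidationError(f"coupling pair must join two distinct regions, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class TaskParadigm:
    """Block-design timing: ``n_epochs`` repetitions of task then rest.

    The default values describe the standard covert word-generation
    protocol: eight 20 s stimulation blocks, each followed by 30 s of rest,
    sampled at TR = 2.5 s (160 time points in total).
    """

    n_epochs: int = 8
    task_s: float = 20.0
    rest_s: float = 30.0
    tr_s: float = 2.5
    task_first: bool = True

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValidationError(f"n_epochs must be >= 1, got {self.n_epochs}")
        if self.task_s <= 0:
            raise ValidationError(f"task_s must be > 0, got {self.task_s}")
        if self.rest_s < 0:
            raise ValidationError(f"rest_s must be >= 0, got {self.rest_s}")
        if self.tr_s <= 0:
            raise ValidationError(f"tr_s must be > 0, got {self.tr_s}")
        n = self.duration_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"total duration {self.duration_s} s is not a multiple of TR {self.tr_s} s"
            )

    @property
    def epoch_s(self) -> float:
        return self.task_s + self.rest_s

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration_s / self.tr_s))

    def boxcar(self) -> np.ndarray:
        """Unit boxcar sampled at TR: 1 during task frames, 0 during rest."""
        t = np.arange(self.n_timepoints) * self.tr_s
        phase = np.mod(t, self.epoch_s)
        if self.task_first:
            on = phase < self.task_s
        else:
            on = phase >= self.rest_s
        return on.astype(float)


_CONNECTIVITIES = (6, 18, 26)


@dataclass
class AnalysisConfig:
    """All thresholds and knobs of the analysis chain.

    Parameters mirror the published processing rules: voxel threshold
    p < 0.001, cluster-level FWE 0.05, exclusion of voxels whose temporal SD
    exceeds 8% of their mean, 4 mm FWHM spatial smoothing, and 15 occupancy
    bins.  ``corr_threshold`` (theta, on \\|C_ij\\|) is not fixed by the
    published method and defaults to 0.6; group comparisons must share one
    value.
    """

    p_voxel: float = 0.001
    fwe_alpha: float = 0.05
    sd_fraction: float = 0.08
    smooth_fwhm_mm: float = 4.0
    corr_threshold: float = 0.6
    common_retention: float = 1.0
    n_bins: int = 15
    hrf_peak_s: float = 5.0
    hrf_sd_s: float = 2.5
    n_null: int = 1000
    connectivity: int = 6
    detrend: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("p_voxel", "fwe_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.sd_fraction <= 0:
            raise ValidationError(f"sd_fraction must be > 0, got {self.sd_fraction}")
        if self.smooth_fwhm_mm < 0:
            raise ValidationError(f"smooth_fwhm_mm must be >= 0, got {self.smooth_fwhm_mm}")
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValidationError(
                f"corr_threshold must lie in (0, 1], got {self.corr_threshold}"
            )
        if not (0.0 < self.common_retention <= 1.0):
            raise ValidationError(
                f"common_retention must lie in (0, 1], got {self.common_retention}"
            )
        if self.n_bins < 1:
            raise ValidationError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.hrf_peak_s <= 0 or self.hrf_sd_s <= 0:
            raise ValidationError("hrf_peak_s and hrf_sd_s must be > 0")
        if self.n_null < 1:
            raise ValidationError(f"n_null must be >= 1, got {self.n_null}")
        if self.connectivity not in _CONNECTIVITIES:
            raise ValidationError(
                f"connectivity must be one of {_CONNECTIVITIES}, got {self.connectivity}"
            )
        if self.seed < 0:
            raise ValidationError("seed must be a nonnegative integer")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        """Stable hash identifying this configuration (used in output tables)."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RegionSpec:
    """One planted region: a cuboid or sphere of voxels with a task amplitude.

    ``beta`` scales the HRF-convolved task signal, ``within_coupling`` the
    region-wide shared latent series.  ``excluded`` marks regions (visual
    cortex) that activate for paradigm-delivery reasons and are discarded
    from the network analysis.
    """

    name: str
    label_id: int
    shape: str  # "cuboid" | "sphere"
    origin: tuple[int, int, int]  # cuboid lower corner / sphere centre
    extent: tuple[int, int, int] | float  # cuboid size per axis / sphere radius
    beta: float = 0.0
    within_coupling: float = 0.0
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.label_id < 1:
            raise ValidationError(f"label_id must be >= 1, got {self.label_id}")
        if self.shape not in ("cuboid", "sphere"):
            raise ValidationError(f"shape must be 'cuboid' or 'sphere', got {self.shape!r}")
        if self.beta < 0 or self.within_coupling < 0:
            raise ValidationError("beta and within_coupling must be >= 0")

    def voxel_indices(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Integer (n, 3) voxel coordinates of the region; validates bounds."""
        if self.shape == "cuboid":
            lo = np.asarray(self.origin, dtype=int)
            size = np.asarray(self.extent, dtype=int)
            if np.any(size < 1):
                raise ValidationError(f"region {self.name}: cuboid extent must be >= 1")
            hi = lo + size
            if np.any(lo < 0) or np.any(hi > np.asarray(grid_shape)):
                raise ValidationError(f"region {self.name} exceeds the grid {grid_shape}")
            axes = [np.arange(lo[d], hi[d]) for d in range(3)]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
            return grid.reshape(-1, 3)
        centre = np.asarray(self.origin, dtype=float)
        radius = float(self.extent)  # type: ignore[arg-type]
        if radius <= 0:
            raise ValidationError(f"region {self.name}: sphere radius must be > 0")
        lo = np.maximum(np.floor(centre - radius).astype(int), 0)
        hi = np.minimum(np.ceil(centre + radius).astype(int) + 1, np.asarray(grid_shape))
        if np.any(lo >= hi):
            raise ValidationError(f"region {self.name} lies outside the grid {grid_shape}")
        axes = [np.arange(lo[d], hi[d]) for d in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        keep = np.linalg.norm(grid - centre, axis=1) <= radius
        vox = grid[keep]
        if np.any(vox < 0) or np.any(vox >= np.asarray(grid_shape)):
            raise ValidationError(f"region {self.name} exceeds the grid {grid_shape}")
        return vox


@dataclass
class SyntheticConfig:
    """Generative model for a multi-subject block-design BOLD dataset.

    Each voxel in region *m* follows::

        x(t) = baseline + beta_m * s(t) + a_m * z_m(t)
               + sum_n c_mn * g_mn(t) + eps(t)

    where ``s`` is the HRF-convolved boxcar, ``z_m`` is a unit-variance
    latent shared by the whole region, ``g_mn`` a unit-variance latent
    shared by every voxel of the coupled region pair (amplitude ``c_mn`` =
    ``between_coupling``), and ``eps`` white noise with sd ``noise_sd``.
    Background voxels receive baseline + noise only.

    Each voxel's latent loadings (``a_m`` and every ``c_mn``) are further
    multiplied by independent unit-mean lognormal factors with log-sd
    ``voxel_jitter_sd``: real fROIs are not homogeneously coupled, and this
    heterogeneity is what gives the thresholded networks their graded
    cross-region link densities instead of all-or-nothing blocks.  All
    amplitudes are additionally scaled per subject by one lognormal factor
    with log-sd ``subject_jitter_sd`` (inter-subject variability).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 4.0
    paradigm: TaskParadigm = field(default_factory=TaskParadigm)
    regions: tuple[RegionSpec, ...] = ()
    between_coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline: float = 100.0
    subject_jitter_sd: float = 0.1
    voxel_jitter_sd: float = 0.6
    hrf_peak_s: float = 5.0
    hrf_sd_s: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.between_coupling = {pair_key(*k): float(v) for k, v in self.between_coupling.items()}
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be > 0")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.subject_jitter_sd < 0:
            raise ValidationError("subject_jitter_sd must be >= 0")
        if self.voxel_jitter_sd < 0:
            raise ValidationError("voxel_jitter_sd must be >= 0")
        if self.seed < 0:
            raise ValidationError("seed must be a nonnegative integer")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValidationError("region names must be unique")
        ids = [r.label_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValidationError("region label_ids must be unique")
        occupied: np.ndarray | None = None
        for region in self.regions:
            vox = region.voxel_indices(self.grid_shape)
            flat = np.ravel_multi_index(vox.T, self.grid_shape)
            if occupied is not None and np.intersect1d(flat, occupied).size:
                raise ValidationError(f"region {region.name} overlaps another region")
            occupied = flat if occupied is None else np.concatenate([occupied, flat])
        for (a, b), c in self.between_coupling.items():
            if a not in names or b not in names:
                raise ValidationError(f"coupling ({a}, {b}) names an unknown region")
            if not np.isfinite(c) or c < 0:
                raise ValidationError(f"coupling ({a}, {b}) must be finite and >= 0, got {c}")

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["between_coupling"] = {f"{a}|{b}": v for (a, b), v in self.between_coupling.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["paradigm"] = TaskParadigm(**d["paradigm"])
        regions = []
        for r in d["regions"]:
            r["origin"] = tuple(r["origin"])
            if isinstance(r["extent"], list):
                r["extent"] = tuple(r["extent"])
            regions.append(RegionSpec(**r))
        d["regions"] = tuple(regions)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["between_coupling"] = {
            tuple(k.split("|")): v for k, v in d["between_coupling"].items()
        }
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    # -- convenience -----------------------------------------------------
    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def coupling(self, a: str, b: str) -> float:
        return self.between_coupling.get(pair_key(a, b), 0.0)

    def coupling_ranking(self) -> list[set[tuple[str, str]]]:
        """Descending order of between-couplings; exact ties grouped in sets."""
        by_value: dict[float, set[tuple[str, str]]] = {}
        for pair, c in self.between_coupling.items():
            by_value.setdefault(c, set()).add(pair)
        return [by_value[v] for v in sorted(by_value, reverse=True)]
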