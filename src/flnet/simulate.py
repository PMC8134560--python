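"""Synthetic multi-subject block-design BOLD data with planted structure.

The generator exists so the whole analysis chain can be exercised against a
known ground truth: active regions with controllable task amplitudes, a
shared latent series per region (within-region coherence) and per coupled
region pair (inter-region coherence whose amplitude hierarchy the analysis
should recover), white measurement noise, an anatomical label volume, and
per-subject lognormal amplitude jitter.

It deliberately omits physiological noise, motion and EPI distortion; see
docs/methods.md for what this does and does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import SubjectScan, hrf_regressor
from .config import AnalysisConfig, SyntheticConfig, ValidationError, pair_key
from .networks import LabelMap

__all__ = ["GroundTruth", "SubjectData", "GroupData", "simulate_subject", "simulate_group"]


@dataclass
class GroundTruth:
    """Planted parameters for one simulated subject (after dropout and jitter)."""

    labels: np.ndarray  # 3D integer label volume
    names: dict[int, str]
    excluded_ids: frozenset[int]
    betas: dict[str, float]
    within_coupling: dict[str, float]
    between_coupling: dict[tuple[str, str], float]
    ranking: list[set[tuple[str, str]]]
    dropout: tuple[str, ...] = ()
    jitter_factor: float = 1.0

    def active_regions(self) -> list[str]:
        return [n for n, b in self.betas.items() if b > 0]


@dataclass
class SubjectData:
    scan: SubjectScan
    label_map: LabelMap
    truth: GroundTruth


@dataclass
class GroupData:
    group: str
    subjects: list[SubjectData]
    config: SyntheticConfig
    subject_seeds: list[int] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _label_volume(config: SyntheticConfig) -> tuple[np.ndarray, dict[int, str], frozenset[int]]:
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    names: dict[int, str] = {}
    excluded: set[int] = set()
    for region in config.regions:
        vox = region.voxel_indices(config.grid_shape)
        labels[tuple(vox.T)] = region.label_id
        names[region.label_id] = region.name
        if region.excluded:
            excluded.add(region.label_id)
    return labels, names, frozenset(excluded)


def simulate_subject(
    config: SyntheticConfig,
    subject_seed: int,
    dropout: tuple[str, ...] = (),
    subject_id: str = "",
    group_id: str = "",
) -> SubjectData:
    """Simulate one subject's 4D scan, label volume and ground truth.

    ``dropout`` names regions that are functionally silent in this subject
    (task amplitude and all couplings zeroed; the anatomical label stays).
    The same (config, subject_seed, dropout) is bit-reproducible.
    """
    config.validate()
    if subject_seed < 0:
        raise ValidationError("subject_seed must be a nonnegative integer")
    for name in dropout:
        config.region(name)  # KeyError on unknown names
    paradigm = config.paradigm
    T = paradigm.n_timepoints
    if T < 2:
        raise ValidationError("paradigm must yield at least 2 time points")

    hrf_cfg = AnalysisConfig(hrf_peak_s=config.hrf_peak_s, hrf_sd_s=config.hrf_sd_s)
    s = hrf_regressor(paradigm, hrf_cfg)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_seed]))
    jitter = float(np.exp(rng.normal(0.0, config.subject_jitter_sd))) if config.subject_jitter_sd > 0 else 1.0

    # latent draw order is fixed (region list order, then sorted pairs) so
    # that identical seeds give identical data regardless of dict ordering
    region_latents = {r.name: rng.standard_normal(T) for r in config.regions}
    pair_latents = {
        pair: rng.standard_normal(T) for pair in sorted(config.between_coupling)
    }

    data = config.baseline + config.noise_sd * rng.standard_normal((*config.grid_shape, T))

    dropped = set(dropout)
    betas: dict[str, float] = {}
    within: dict[str, float] = {}
    between: dict[tuple[str, str], float] = {}
    for pair, c in config.between_coupling.items():
        if pair[0] in dropped or pair[1] in dropped:
            between[pair] = 0.0
        else:
            between[pair] = jitter * c

    sigma_v = config.voxel_jitter_sd

    def _loadings(rng: np.random.Generator, n: int) -> np.ndarray:
        # unit-mean lognormal per-voxel loading heterogeneity
        if sigma_v == 0:
            return np.ones(n)
        return rng.lognormal(mean=-0.5 * sigma_v**2, sigma=sigma_v, size=n)

    for region in config.regions:
        vox = region.voxel_indices(config.grid_shape)
        n_vox = len(vox)
        # loading draws happen for every region (dropped or not) so that a
        # dropout subject consumes the same random stream as the others
        eta_within = _loadings(rng, n_vox)
        eta_between = {
            pair: _loadings(rng, n_vox)
            for pair in sorted(config.between_coupling)
            if region.name in pair
        }
        if region.name in dropped:
            betas[region.name] = 0.0
            within[region.name] = 0.0
            continue
        betas[region.name] = jitter * region.beta
        within[region.name] = jitter * region.within_coupling
        signal = np.outer(np.full(n_vox, betas[region.name]), s)
        if within[region.name] > 0:
            signal += np.outer(within[region.name] * eta_within, region_latents[region.name])
        for pair, c in between.items():
            if region.name in pair and c > 0:
                signal += np.outer(c * eta_between[pair], pair_latents[pair])
        data[tuple(vox.T)] += signal

    labels, names, excluded = _label_volume(config)
    scan = SubjectScan(data, config.voxel_size_mm, paradigm, subject_id, group_id)
    truth = GroundTruth(
        labels=labels,
        names=names,
        excluded_ids=excluded,
        betas=betas,
        within_coupling=within,
        between_coupling=between,
        ranking=config.coupling_ranking(),
        dropout=tuple(dropout),
        jitter_factor=jitter,
    )
    label_map = LabelMap(labels, names, excluded)
    return SubjectData(scan, label_map, truth)


def simulate_group(
    config: SyntheticConfig,
    n_subjects: int,
    group_seed: int,
    dropout: dict[int, tuple[str, ...]] | None = None,
    group: str = "",
) -> GroupData:
    """Simulate ``n_subjects`` subjects sharing geometry and coupling structure.

    Per-subject seeds are derived deterministically from ``group_seed``.
    ``dropout`` maps subject index (0-based) to region names silenced in
    that subject, which lets tests plant e.g. a V structure in m of n
    subjects.
    """
    if n_subjects < 1:
        raise ValidationError(f"n_subjects must be >= 1, got {n_subjects}")
    if group_seed < 0:
        raise ValidationError("group_seed must be a nonnegative integer")
    dropout = dropout or {}
    for idx in dropout:
        if not (0 <= idx < n_subjects):
            raise ValidationError(f"dropout subject index {idx} outside 0..{n_subjects - 1}")
    seeds = [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(group_seed).generate_state(n_subjects)]
    subjects = [
        simulate_subject(
            config,
            seeds[i],
            dropout.get(i, ()),
            subject_id=f"{group or 'group'}-s{i:02d}",
            group_id=group,
        )
        for i in range(n_subjects)
    ]
    return GroupData(group, subjects, config, seeds)
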