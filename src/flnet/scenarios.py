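"""Canned synthetic study configurations.

These builders encode the study conditions every downstream demonstration
and calibration run uses: the block-design paradigm (8 epochs of 20 s task
+ 30 s rest at TR 2.5 s → 160 frames), a 24x24x12 grid of 4 mm voxels,
cuboidal 4x4x4 planted regions named after the language areas (pre-SMA,
BA(L), v-preMA(L), WA(L), a peripheral SupraMG(L) and an excluded visual
region), and coupling amplitudes chosen from the closed-form correlation
ladder of the generative model (derivation in docs/methods.md).

Two analysis thresholds are used, each fixed per study: theta = 0.40 for
the link-weight-hierarchy studies and theta = 0.50 for the k-shell
core/periphery studies.  Within a study every group shares one theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .config import AnalysisConfig, RegionSpec, SyntheticConfig, TaskParadigm

__all__ = [
    "REGION_ROLES",
    "HIERARCHY_COUPLINGS",
    "hierarchy_study",
    "core_periphery_study",
    "wa_contrast_study",
    "table1_study",
    "null_config",
    "Table1Study",
]

#: region name -> functional role used by the structure detector
REGION_ROLES: dict[str, str] = {
    "pre-SMA": "preSMA",
    "BA(L)": "BA",
    "v-preMA(L)": "preMA",
    "WA(L)": "WA",
}

#: planted coupling ladder for the five named core links, adjacent ratios 1.5
HIERARCHY_COUPLINGS: dict[str, float] = {
    "A": 2.66,  # BA(L) - v-preMA(L)
    "B": 1.77,  # pre-SMA - v-preMA(L)
    "C": 1.18,  # pre-SMA - BA(L)
    "D": 0.79,  # BA(L) - WA(L)
    "E": 0.53,  # WA(L) - v-preMA(L)
}

_GRID = (24, 24, 12)
_CUBE = (4, 4, 4)

# cuboid origins, pairwise separated by >= 6 voxels in at least one axis
_ORIGINS = {
    "pre-SMA": (2, 2, 2),
    "BA(L)": (2, 12, 2),
    "v-preMA(L)": (12, 2, 2),
    "WA(L)": (12, 12, 2),
    "SupraMG(L)": (18, 18, 6),
    "visual": (18, 2, 6),
}


def _region(name: str, label_id: int, beta: float, within: float, excluded: bool = False) -> RegionSpec:
    return RegionSpec(
        name=name,
        label_id=label_id,
        shape="cuboid",
        origin=_ORIGINS[name],
        extent=_CUBE,
        beta=beta,
        within_coupling=within,
        excluded=excluded,
    )


def _core_links(c: dict[str, float]) -> dict[tuple[str, str], float]:
    return {
        ("BA(L)", "v-preMA(L)"): c["A"],
        ("pre-SMA", "v-preMA(L)"): c["B"],
        ("pre-SMA", "BA(L)"): c["C"],
        ("BA(L)", "WA(L)"): c["D"],
        ("WA(L)", "v-preMA(L)"): c["E"],
    }


def hierarchy_study(seed: int = 0, couplings: dict[str, float] | None = None) -> tuple[SyntheticConfig, AnalysisConfig]:
    """Four core regions with the planted A > B > C > D > E coupling ladder.

    WA(L)'s within-region amplitude (1.549) tops up its variance so that the
    planted coupling order maps onto a monotone inter-region correlation
    order despite WA carrying far less coupling variance than the triangle
    regions; the other regions use the baseline 0.6.
    """
    c = dict(HIERARCHY_COUPLINGS if couplings is None else couplings)
    synth = SyntheticConfig(
        grid_shape=_GRID,
        voxel_size_mm=4.0,
        paradigm=TaskParadigm(),
        regions=(
            _region("pre-SMA", 1, beta=3.0, within=0.6),
            _region("BA(L)", 2, beta=3.0, within=0.6),
            _region("v-preMA(L)", 3, beta=3.0, within=0.6),
            _region("WA(L)", 4, beta=3.0, within=1.549),
        ),
        between_coupling=_core_links(c),
        noise_sd=1.0,
        baseline=100.0,
        seed=seed,
    )
    analysis = AnalysisConfig(corr_threshold=0.40, n_null=200, seed=seed)
    return synth, analysis


def core_periphery_study(seed: int = 0) -> tuple[SyntheticConfig, AnalysisConfig]:
    """Dense triangle couplings, weakly attached WA: planted core/periphery.

    The triangle regions are strongly coupled pairwise (1.5) and form the
    innermost shells; WA(L) has a reduced task amplitude (1.5, still easily
    detected) and weak couplings (0.4) so its voxels occupy mid/low shells.
    """
    tri = 1.5
    synth = SyntheticConfig(
        grid_shape=_GRID,
        voxel_size_mm=4.0,
        paradigm=TaskParadigm(),
        regions=(
            _region("pre-SMA", 1, beta=3.0, within=0.6),
            _region("BA(L)", 2, beta=3.0, within=0.6),
            _region("v-preMA(L)", 3, beta=3.0, within=0.6),
            _region("WA(L)", 4, beta=1.5, within=0.6),
        ),
        between_coupling={
            ("pre-SMA", "BA(L)"): tri,
            ("pre-SMA", "v-preMA(L)"): tri,
            ("BA(L)", "v-preMA(L)"): tri,
            ("BA(L)", "WA(L)"): 0.4,
            ("WA(L)", "v-preMA(L)"): 0.4,
        },
        noise_sd=1.0,
        baseline=100.0,
        seed=seed,
    )
    analysis = AnalysisConfig(corr_threshold=0.50, n_null=200, seed=seed)
    return synth, analysis


def wa_contrast_study(seed: int = 0, wa_coupling: float = 1.2) -> tuple[SyntheticConfig, AnalysisConfig]:
    """Like :func:`core_periphery_study` but with WA coupling as the contrast dial.

    ``wa_coupling=1.2`` plants a strongly attached WA; ``wa_coupling=0.0``
    detaches it entirely.  Two groups generated with these two settings
    differ *only* in the WA links.
    """
    synth, analysis = core_periphery_study(seed)
    coupling = dict(synth.between_coupling)
    coupling[("BA(L)", "WA(L)")] = wa_coupling
    coupling[("WA(L)", "v-preMA(L)")] = wa_coupling
    synth = replace(synth, between_coupling=coupling)
    return synth, analysis


@dataclass
class Table1Study:
    """Three groups x 8 subjects emulating the published cohort layout.

    The V structure is planted by region dropout (WA(L) functionally silent
    in a subject): 2 of 8 monolingual subjects, 4 of 8 bilingual subjects
    in the second language, none in the native language group.
    """

    synthetic: SyntheticConfig
    analysis: AnalysisConfig
    groups: dict[str, dict] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=lambda: dict(REGION_ROLES))


def table1_study(seed: int = 0, n_subjects: int = 8) -> Table1Study:
    """Cohort emulation with peripheral and excluded regions included."""
    synth, analysis = hierarchy_study(seed)
    regions = synth.regions + (
        _region("SupraMG(L)", 5, beta=2.0, within=0.6),
        _region("visual", 6, beta=4.0, within=0.6, excluded=True),
    )
    synth = replace(synth, regions=regions)
    # majority-rule retention; theta relaxed to 0.35 so the weakest planted
    # link (E) is expressed in every subject that carries it, making the
    # structure frequencies reflect the planted dropout pattern alone
    analysis = replace(analysis, common_retention=0.5, corr_threshold=0.35)
    wa_dropout = {
        "monolingual": (2, 5),
        "bilingual-L2": (1, 3, 5, 7),
        "bilingual-L1": (),
    }
    groups = {
        name: {
            "n_subjects": n_subjects,
            "group_seed": seed * 1000 + i,
            "dropout": {idx: ("WA(L)",) for idx in idxs if idx < n_subjects},
        }
        for i, (name, idxs) in enumerate(wa_dropout.items())
    }
    return Table1Study(synth, analysis, groups)


def null_config(seed: int = 0, grid_shape: tuple[int, int, int] = _GRID) -> SyntheticConfig:
    """No regions, no couplings: pure baseline + white noise (null data)."""
    return SyntheticConfig(
        grid_shape=grid_shape,
        voxel_size_mm=4.0,
        paradigm=TaskParadigm(),
        regions=(),
        between_coupling={},
        noise_sd=1.0,
        baseline=100.0,
        seed=seed,
    )
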