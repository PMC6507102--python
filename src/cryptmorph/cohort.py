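"""Cohort-level dataset generation: cohorts > mice > locations > depth stacks.

The study design places mice in treatment cohorts, images each mouse's
tissue at one to three locations, and acquires a five-plane depth stack
(20-100 um in 20 um steps) at each location.  ``generate_cohort_dataset``
reproduces that hierarchy with synthetic scenes, fully determined by the
design's global seed.

``study_design()`` returns the published design arithmetic: five cohorts
with 9/6/3/4/9 mice (31 total) contributing 9/8/9/5/12 stacks (43 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .scenes import SyntheticScene, generate_depth_stack, preset

DEFAULT_DEPTHS_UM = (20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: mice, total stacks, phenotype preset, depths."""

    name: str
    n_mice: int
    n_stacks: int
    phenotype: str = "normal"
    depths_um: tuple[float, ...] = DEFAULT_DEPTHS_UM
    images_per_location: int = 1

    def stacks_per_mouse(self) -> list[int]:
        """Allocate total stacks across mice, 1-3 per mouse.

        Stacks are spread as evenly as possible; the first
        ``n_stacks % n_mice`` mice receive one extra.
        """
        if self.n_mice <= 0:
            raise ValueError(f"cohort {self.name!r} has no mice")
        base, rem = divmod(self.n_stacks, self.n_mice)
        alloc = [base + 1 if i < rem else base for i in range(self.n_mice)]
        if min(alloc) < 1 or max(alloc) > 3:
            raise ValueError(
                f"cohort {self.name!r}: {self.n_stacks} stacks over "
                f"{self.n_mice} mice leaves a mouse outside the 1-3 "
                "stacks-per-mouse range"
            )
        return alloc


@dataclass(frozen=True)
class CohortDesign:
    """Full experiment design plus scene-parameter overrides and seed."""

    cohorts: tuple[CohortSpec, ...] = ()
    seed: int = 0
    scene_overrides: dict = field(default_factory=dict)

    @property
    def total_mice(self) -> int:
        return sum(c.n_mice for c in self.cohorts)

    @property
    def total_stacks(self) -> int:
        return sum(c.n_stacks for c in self.cohorts)


@dataclass
class SceneRecord:
    """One generated scene with its position in the hierarchy."""

    cohort: str
    mouse: str
    location: str
    depth_um: float
    image_id: str
    scene: SyntheticScene


@dataclass
class CohortDataset:
    """All generated scenes for a design."""

    design: CohortDesign
    records: list[SceneRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SceneRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Metadata table: one row per scene."""
        return pd.DataFrame(
            [
                dict(
                    cohort=r.cohort,
                    mouse=r.mouse,
                    location=r.location,
                    depth_um=r.depth_um,
                    image_id=r.image_id,
                    crypt_count=len(r.scene.truth.crypts),
                    shortfall=r.scene.shortfall,
                )
                for r in self.records
            ]
        )


def generate_cohort_dataset(design: CohortDesign) -> CohortDataset:
    """Generate every scene of a cohort design, reproducibly.

    Each stack gets its own seed drawn from one generator seeded by the
    design's global seed, so the whole dataset is a pure function of the
    design.  Scene metadata carries cohort / mouse / location / depth
    labels for downstream summaries and nested ANOVA.
    """
    for c in design.cohorts:
        if c.n_mice <= 0:
            raise ValueError(f"cohort {c.name!r} has zero mice")
    master = np.random.default_rng(np.random.SeedSequence(design.seed))
    records: list[SceneRecord] = []
    for c in design.cohorts:
        alloc = c.stacks_per_mouse()
        for m_idx, n_stacks in enumerate(alloc, start=1):
            mouse = f"{c.name}/m{m_idx:02d}"
            for loc_idx in range(1, n_stacks + 1):
                location = f"{mouse}/loc{loc_idx}"
                for rep in range(c.images_per_location):
                    stack_seed = int(master.integers(2**31))
                    params = preset(
                        c.phenotype, seed=stack_seed, **design.scene_overrides
                    )
                    scenes = generate_depth_stack(
                        params,
                        list(c.depths_um),
                        metadata=dict(cohort=c.name, mouse=mouse, location=location),
                    )
                    for scene in scenes:
                        depth = scene.image.metadata["depth_um"]
                        image_id = f"{location}/z{int(depth):03d}"
                        if c.images_per_location > 1:
                            image_id += f"/r{rep}"
                        scene.image.metadata["image_id"] = image_id
                        records.append(
                            SceneRecord(
                                cohort=c.name,
                                mouse=mouse,
                                location=location,
                                depth_um=depth,
                                image_id=image_id,
                                scene=scene,
                            )
                        )
    return CohortDataset(design=design, records=records)


def study_design(seed: int = 0, **scene_overrides) -> CohortDesign:
    """The full study design: 31 mice contributing 43 five-plane depth stacks.

    Control mice image normal mucosa; treated cohorts image
    tumor-adjacent regions (tumors themselves show no crypt structure
    and are not informative for crypt morphometry).
    """
    return CohortDesign(
        cohorts=(
            CohortSpec("Control", n_mice=9, n_stacks=9, phenotype="normal"),
            CohortSpec("AOM early", n_mice=6, n_stacks=8, phenotype="tumor_adjacent"),
            CohortSpec("AOM late", n_mice=3, n_stacks=9, phenotype="tumor_adjacent"),
            CohortSpec("AOM-DSS early", n_mice=4, n_stacks=5, phenotype="tumor_adjacent"),
            CohortSpec("AOM-DSS late", n_mice=9, n_stacks=12, phenotype="tumor_adjacent"),
        ),
        seed=seed,
        scene_overrides=scene_overrides,
    )


def demo_design(seed: int = 0) -> CohortDesign:
    """A small design for demos and determinism checks.

    Five cohorts x 2 mice x 1 stack on 128 px fields with proportionally
    fewer, smaller crypts, so the full pipeline runs in seconds.
    """
    cohorts = tuple(
        CohortSpec(
            name,
            n_mice=2,
            n_stacks=2,
            phenotype=ph,
        )
        for name, ph in [
            ("Control", "normal"),
            ("AOM early", "tumor_adjacent"),
            ("AOM late", "tumor_adjacent"),
            ("AOM-DSS early", "tumor_adjacent"),
            ("AOM-DSS late", "tumor_adjacent"),
        ]
    )
    return CohortDesign(
        cohorts=cohorts,
        seed=seed,
        scene_overrides=dict(
            field_size_px=128,
            crypt_count=6,
            lumen_radius_um=(9.0, 1.5),
            min_edge_spacing_um=5.0,
        ),
    )
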