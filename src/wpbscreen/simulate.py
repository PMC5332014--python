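"""End-to-end synthetic screens: generate, analyze, score.

Ties the generator to the full analysis so that screen-level statistics
(B scores, Z scores, Z', replicate SD, hit lists) can be validated against
planted ground truth without any acquired data. The default conditions
emulate one replicate pair of the kinome screen at reduced scale: a
96-well plate per replicate, 8 negative-control wells, 8 positive-control
wells with the vWF-knockdown phenotype (WPB count x0.1, intensity x0.2),
and a handful of planted sample-well hits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pipeline import PlateResult, ScreenResult, process_field, run_screen
from .plateio import PipelineConfig
from .stats import compute_well_features
from .synth import FieldSpec, PlateLayout, default_screen_layout, generate_plate

__all__ = ["SimulatedScreen", "analyze_generated_plate", "run_synthetic_screen"]

#: Planted sample hits used by the default simulated screen: moderate
#: increases in WPB count per cell, >> 3 between-well SDs.
DEFAULT_HIT_WELLS = {
    "A03": {"count": 1.6},
    "C06": {"count": 1.6},
    "F02": {"count": 1.6},
    "H10": {"count": 1.6},
}


@dataclass
class SimulatedScreen:
    layout: PlateLayout
    hit_wells: dict
    replicates: list          # per-replicate well-feature DataFrames
    truth: list               # per-replicate {(well, fov): GroundTruth}
    result: ScreenResult


def analyze_generated_plate(
    layout: PlateLayout,
    spec: FieldSpec,
    config: PipelineConfig,
    plate_id: str,
    wells=None,
) -> tuple[pd.DataFrame, dict]:
    """Generate and analyze a plate in memory; returns (well_features, truth)."""
    by_well: dict[str, list] = {}
    truths = {}
    for well, fov, nuc, wpb, truth in generate_plate(layout, spec, wells=wells):
        res = process_field(nuc, wpb, config, plate=plate_id, well=well, fov=fov)
        by_well.setdefault(well, []).append(res)
        truths[(well, fov)] = truth
    rows = []
    for well, results in sorted(by_well.items()):
        results = sorted(results, key=lambda r: r.fov)
        vec = compute_well_features(
            [r.features for r in results],
            [r.n_cells for r in results],
            feret_cut_um=config.feret_cut_um,
            well=well,
            plate=plate_id,
        )
        rows.append(vec.as_dict())
    return pd.DataFrame(rows), truths


def run_synthetic_screen(
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    n_nuclei: int = 18,
    fields_per_well: int = 1,
    n_replicates: int = 2,
    hit_wells: dict | None = None,
    config: PipelineConfig | None = None,
    base_spec: FieldSpec | None = None,
) -> SimulatedScreen:
    """Simulate and score a replicate set of 96-well plates.

    The per-field nucleus count follows the generator's default confluent
    density scaled to the requested field size. Replicate plates use seeds
    derived from ``seed`` so the whole screen is reproducible from one
    integer.
    """
    if config is None:
        config = PipelineConfig()
    hits = DEFAULT_HIT_WELLS if hit_wells is None else hit_wells
    layout = default_screen_layout(fields_per_well=fields_per_well,
                                   hit_wells=hits)
    if base_spec is None:
        base_spec = FieldSpec(image_shape=image_shape, n_nuclei=n_nuclei)
    rep_seeds = [
        int(s % (2**31 - 1))
        for s in np.random.SeedSequence(int(seed)).generate_state(n_replicates)
    ]
    replicates, truths = [], []
    for i, rep_seed in enumerate(rep_seeds, start=1):
        spec = replace(base_spec, seed=rep_seed)
        feats, truth = analyze_generated_plate(
            layout, spec, config, plate_id=f"plate{i}"
        )
        replicates.append(feats)
        truths.append(truth)
    result = run_screen(replicates, layout.well_roles, config=config)
    return SimulatedScreen(layout=layout, hit_wells=hits, replicates=replicates,
                           truth=truths, result=result)
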