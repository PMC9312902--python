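"""Reference study conditions: the twelve-subject cohort this package models.

The reference cohort consists of six healthy controls (HC) and six
osteoporotic (OP) subjects whose QCT scores (BMD_QCT-L1-3, mg/mL) are fixed
study inputs; synthetic subjects are generated at exactly these densitometric
targets with geometry seeds 1-6 shared between the cohorts, so the only
systematic difference between HC and OP models is bone density.  The
experimental plausibility range for whole-lumbar compressive failure loads of
healthy spines, used as the calibration band for the geometry defaults, is
967-4387 N.
"""

from __future__ import annotations

import dataclasses

from .config import RunConfig
from .simulate import SubjectRecord, run_subject, synthesize_subject

#: Subject-level BMD_QCT-L1-3 scores (mg/mL) of the reference cohort.
HC_BMD_VALUES = (108.04, 107.82, 106.91, 103.86, 82.44, 95.54)
OP_BMD_VALUES = (67.67, 62.44, 61.20, 57.14, 56.44, 62.69)

#: Experimental failure-load plausibility range for healthy lumbar spines (N).
EXPERIMENTAL_FL_RANGE = (967.0, 4387.0)

#: Geometry seeds of the reference cohort (shared between HC and OP).
GEOMETRY_SEEDS = (1, 2, 3, 4, 5, 6)


def run_reference_cohort(
    seed: int = 1,
    config: RunConfig | None = None,
    compression: bool = True,
    motions: tuple[str, ...] = (),
) -> list[SubjectRecord]:
    """Simulate the full twelve-subject reference cohort.

    ``seed`` drives the per-subject CT noise realizations; the geometry seeds
    and BMD targets are fixed study conditions.  Compression is run for every
    subject; ROM motions only when requested (they do not enter the cohort
    failure-load statistics).
    """
    cfg = dataclasses.replace(
        config or RunConfig(), motions=tuple(motions)
    )
    records: list[SubjectRecord] = []
    k = 0
    for cohort, targets in (("HC", HC_BMD_VALUES), ("OP", OP_BMD_VALUES)):
        for gseed, target in zip(GEOMETRY_SEEDS, targets):
            k += 1
            noise_seed = (1000 * seed + k) % (2**31 - 1)
            geom, vol, mask = synthesize_subject(
                target, geometry_seed=gseed, noise_seed=noise_seed, config=cfg
            )
            rec = run_subject(
                vol, mask, cfg, subject_id=f"{cohort}{gseed}",
                compression=compression, keep_curves=bool(motions),
            )
            rec.provenance["target_bmd"] = target
            rec.provenance["geometry_seed"] = gseed
            records.append(rec)
    return records
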