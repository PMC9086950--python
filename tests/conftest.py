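"""Shared fixtures.

The scaled selection-efficacy arms (50 replicates each of several
(mode, h) treatments at the ``figure1_scaled`` preset) are expensive, so
they are simulated once per session and shared between the directionality
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from haplosim.experiment import (
    EQUAL_CHROMOSOMES,
    EQUAL_INDIVIDUALS,
    Treatment,
    TreatmentGrid,
    figure1_scaled_preset,
    run_grid,
)
from haplosim.genome_core import DIPLOID, HAPLODIPLOID


@pytest.fixture(scope="session")
def scaled_arms() -> dict[tuple[str, float], np.ndarray]:
    """Fixation counts per replicate for the scaled advantageous-mutation
    design (s = 0.01), keyed by (arm, h).

    Arms: 'hap' (haplodiploid, 100+100), 'dip_equal_n' (diploid at the
    same census) and 'dip_equal_chrom' (diploid at 75+75, matching the
    haplodiploid arm's 300 genome copies).
    """
    _, template = figure1_scaled_preset(base_seed=202)
    arms: dict[tuple[str, float], np.ndarray] = {}

    def collect(arm: str, mode: str, pairing: str, hs: tuple, base_seed: int):
        grid = TreatmentGrid(
            treatments=[Treatment(f"s0.01_h{h:g}", s=0.01, h=h) for h in hs],
            replicates=50,
            base_seed=base_seed,
            census_pairing=pairing,
            modes=(mode,),
        )
        table = run_grid(grid, template)
        for h in hs:
            sel = table[table["h"] == h].sort_values("replicate")
            arms[(arm, h)] = sel["total_fixations"].to_numpy()

    collect("hap", HAPLODIPLOID, EQUAL_INDIVIDUALS, (0.0, 0.5, 1.0), 11)
    collect("dip_equal_n", DIPLOID, EQUAL_INDIVIDUALS, (0.0, 1.0), 22)
    collect("dip_equal_chrom", DIPLOID, EQUAL_CHROMOSOMES, (0.0, 0.5), 33)
    return arms
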