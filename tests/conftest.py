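"""Shared fixtures: synthetic genomes at desk scale and the five-genome panel."""

from __future__ import annotations

import pytest

from mitocomp.synthetic_data import (
    IntronPlan,
    RepeatPlan,
    SimSpec,
    cyathus5_panel,
    simulate_mitogenome,
)


def small_spec(seed: int = 0, **overrides) -> SimSpec:
    """A compact genome (~22 kb) with the full feature repertoire."""
    defaults = dict(
        genome_bp=32_000,
        trna_count=10,
        n_un_orf=2,
        intron_plan=(
            IntronPlan("cox1", 612, 900, True),
            IntronPlan("cox1", 1305, 700, False),
            IntronPlan("cob", 450, 800, True),
        ),
        repeat_plan=(
            RepeatPlan("interspersed", 200, identity=100.0),
            RepeatPlan("tandem", 12, copies=5),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimSpec(**defaults)


@pytest.fixture(scope="session")
def small_genome():
    """(record, manifest) for a compact default genome."""
    return simulate_mitogenome(small_spec(seed=11))


@pytest.fixture(scope="session")
def panel():
    """(records, manifests, panel_manifest) of the five-genome study panel."""
    return cyathus5_panel(seed=3)
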