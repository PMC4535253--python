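"""Shared fixtures: a small diploid world with planted SNVs and capture kits.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import dataclasses

import pytest

import wgadiff as w


@pytest.fixture(scope="session")
def genome():
    return w.simulate_genome(20_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def diploid(genome):
    haps, truth = w.plant_variants(genome, n_snvs=40, het_fraction=0.5,
                                   min_spacing=60, seed=102)
    return haps, truth


@pytest.fixture(scope="session")
def reference(genome):
    return {genome.name: genome.sequence}


@pytest.fixture(scope="session")
def whole_genome_kit(genome):
    """Single target spanning the genome; isolates read simulation from
    capture geometry."""
    return w.CaptureKit(name="whole", targets=((genome.name, 0, genome.length),),
                        efficiency=1.0)


@pytest.fixture(scope="session")
def clean_readset(diploid, whole_genome_kit):
    haps, _ = diploid
    cfg = w.ReadSimConfig(depth=30.0, base_error_rate=0.001, seed=103)
    return w.simulate_reads(haps, whole_genome_kit, cfg)


@pytest.fixture(scope="session")
def clean_callresult(clean_readset, reference):
    return w.call_pipeline(list(clean_readset.reads1),
                           list(clean_readset.reads2), reference)


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
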