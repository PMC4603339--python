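"""Shared fixtures: a small synthetic study exercised by several suites."""

from __future__ import annotations

import pytest

from homeoseq import assign, synth


@pytest.fixture(scope="session")
def small_cfg() -> synth.SimConfig:
    """Error-free miniature study at the default homoeolog divergence."""
    return synth.SimConfig(
        n_genes=60,
        reads_per_library=600,
        seq_error_rate=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return synth.simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_sams(small_study, tmp_path_factory):
    """Per-subgenome SAMs for one library of the small study."""
    (ref_a, ref_b), _, libraries, _, _, truth, _ = small_study
    pairs = libraries["wild_1"]
    outdir = tmp_path_factory.mktemp("sams")
    sam_a = outdir / "wild_1_A.sam"
    sam_b = outdir / "wild_1_B.sam"
    synth.write_sam(synth.fixture_align(pairs, ref_a), ref_a, sam_a)
    synth.write_sam(synth.fixture_align(pairs, ref_b), ref_b, sam_b)
    return sam_a, sam_b, truth


@pytest.fixture(scope="session")
def small_partition(small_sams):
    sam_a, sam_b, truth = small_sams
    decisions, stats = assign.partition_library(sam_a, sam_b)
    return decisions, stats, truth
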