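from __future__ import annotations

from dataclasses import dataclass

import pytest

from ampliphase.align import align_reads
from ampliphase.amplicon import AmpliconReference, build_default_reference
from ampliphase.genotype import call_genotypes, extract_alleles
from ampliphase.simulate import (
    MoleculePool,
    PcrConfig,
    ReadModel,
    simulate_pcr,
    simulate_reads,
)
from ampliphase.star import DEFAULT_STAR_TABLE


@dataclass
class SampleRun:
    """One simulated sample carried through align -> genotype."""

    reference: AmpliconReference
    pool: MoleculePool
    reads: list
    truths: list
    records: list
    table: object
    calls: list


def _run_sample(reference, diplotype, *, cycles, chimera_rate0, model, n_reads, seed):
    haps = (DEFAULT_STAR_TABLE[diplotype[0]], DEFAULT_STAR_TABLE[diplotype[1]])
    pool = simulate_pcr(
        haps,
        PcrConfig(cycles=cycles, chimera_rate0=chimera_rate0, seed=seed),
    )
    reads, truths = simulate_reads(pool, reference, n_reads, model, seed=seed + 1)
    records = align_reads(reads, reference)
    table = extract_alleles(records, reads, reference)
    calls = call_genotypes(table, reference)
    return SampleRun(reference, pool, reads, truths, records, table, calls)


@pytest.fixture(scope="session")
def reference() -> AmpliconReference:
    return build_default_reference(1)


@pytest.fixture(scope="session")
def clean_run(reference) -> SampleRun:
    """Error-free, chimera-free *A1/*B1b sample (het at all six SNPs)."""
    return _run_sample(
        reference,
        ("*A1", "*B1b"),
        cycles=25,
        chimera_rate0=0.0,
        model=ReadModel(0.0, 0.0, 0.0),
        n_reads=1500,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_run(reference) -> SampleRun:
    """Default-error, default-chimera *A1/*B1b sample."""
    return _run_sample(
        reference,
        ("*A1", "*B1b"),
        cycles=40,
        chimera_rate0=0.5,
        model=ReadModel(),
        n_reads=3000,
        seed=23,
    )
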