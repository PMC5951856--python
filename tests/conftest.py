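"""Shared fixtures: tiny deterministic datasets used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from secmut.records import MutationRecord
from secmut.signatures import ExposureProfile, SignatureCatalog
from secmut.somatic_calling import Read
from secmut.synthetic_data import gen_signature_catalog


def make_reads(bases: str, q: float = 40.0, mq: float = 60.0) -> list[Read]:
    """Pileup reads with uniform qualities from a base string like 'AAAAT'."""
    return [Read(base=b, base_quality=q, mapping_quality=mq) for b in bases]


def make_snv(chrom="chr1", pos=100, ref="C", alt="T", context=None, **kw) -> MutationRecord:
    if context is None and ref in "ACGT" and len(ref) == 1:
        context = "A" + ref + "A"
    return MutationRecord(chrom, pos, ref, alt, "SNV", context=context, **kw)


def make_exposures(fractions: dict[str, float], total: int = 1000) -> ExposureProfile:
    ids = tuple(fractions)
    arr = np.array([fractions[i] for i in ids], dtype=float)
    return ExposureProfile(
        ids=ids,
        fractions=arr,
        attributed_counts=arr * total,
        residual_norm=0.0,
    )


@pytest.fixture(scope="session")
def sparse_catalog() -> SignatureCatalog:
    """Two near-disjoint synthetic signatures (easy-recovery regime)."""
    return gen_signature_catalog(2, concentration=0.01, seed=42)


@pytest.fixture(scope="session")
def clean_record() -> MutationRecord:
    """A somatic SNV passing all ten site filters."""
    return make_snv(
        tumor_depth=80,
        normal_depth=60,
        tumor_alt_depth=30,
        normal_alt_depth=0,
        mq0_reads=0,
        alt_fwd=15,
        alt_rev=15,
        mismatch_quality_sum=5.0,
        avg_mismatches=0.5,
        dist_to_3prime=0.5,
        somatic_score=40.0,
        genotype_quality=80.0,
        alt_allele_support={"T": 30},
    )
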