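"""Forward simulators for every input the pipeline consumes.

The real cohort behind this pipeline is controlled-access, so each analysis
stage is exercised on synthetic data with known ground truth: mutation
catalogs drawn from known signature mixtures, microsatellite repeat-length
tables with a set per-locus instability rate, exon coverage/allele-fraction
profiles generated from a known purity, ploidy and segment list, per-site
read metrics for the filter engine, and expression matrices with group
structure.  All generators are deterministic given their parameters and seed.

Noise models are deliberately the simplest consistent with the downstream
Gaussian/t-test treatment: multinomial channel sampling for spectra, Gaussian
noise for coverage and allele fractions (folded at 0.5 for majority
fractions), Poisson depths, and Bernoulli corruption of filter metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS, N_CHANNELS, reverse_complement
from .records import ExonStat, MicrosatelliteLocus, MutationRecord, RepeatLengthDistribution
from .signatures import SignatureCatalog
from .somatic_calling import FILTER_NAMES

DEFAULT_CAPTURE_MB = 62.52


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one synthetic dataset."""

    seed: int
    signature_exposures: dict[str, float] = field(default_factory=dict)
    indel_fraction: float = 0.0
    msi_locus_instability: float = 0.0
    purity_alpha: float = 1.0
    tumor_ploidy: float = 2.0
    segment_truth: list[tuple[str, int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.signature_exposures:
            total = sum(self.signature_exposures.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("signature exposures must sum to 1")
        for frac in (self.indel_fraction, self.msi_locus_instability):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if not (0.0 < self.purity_alpha <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if self.tumor_ploidy <= 0:
            raise ValueError("ploidy must be positive")


# ---------------------------------------------------------------------------
# Signature catalogs and mutation catalogs
# ---------------------------------------------------------------------------

def gen_signature_catalog(
    n_signatures: int,
    concentration: float = 0.05,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> SignatureCatalog:
    """Random signature basis: Dirichlet rows over the 96 channels.

    Small ``concentration`` values give sparse, nearly disjoint signatures
    (the easy-recovery regime resembling real signature catalogs).
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    matrix = rng.dirichlet([concentration] * N_CHANNELS, size=n_signatures)
    if ids is None:
        ids = tuple(str(i + 1) for i in range(n_signatures))
    return SignatureCatalog(matrix, tuple(ids))


def _passing_metrics(rng: np.random.Generator, alt: str, vaf: float) -> dict:
    """Read metrics that pass all ten site filters."""
    depth_t = int(rng.poisson(80)) + 20
    depth_n = int(rng.poisson(60)) + 20
    alt_depth = max(4, min(depth_t, int(rng.binomial(depth_t, vaf))))
    fwd = alt_depth // 2
    return dict(
        tumor_depth=depth_t,
        normal_depth=depth_n,
        tumor_alt_depth=alt_depth,
        normal_alt_depth=0,
        mq0_reads=0,
        alt_fwd=fwd,
        alt_rev=alt_depth - fwd,
        mismatch_quality_sum=float(rng.uniform(0, 10)),
        avg_mismatches=float(rng.uniform(0, 1.0)),
        dist_to_3prime=float(rng.uniform(0.3, 0.7)),
        somatic_score=float(rng.uniform(30, 120)),
        genotype_quality=float(rng.uniform(30, 120)),
        alt_allele_support={alt: alt_depth},
    )


def gen_mutation_catalog(
    catalog: SignatureCatalog,
    exposures: Sequence[float],
    n_snv: int,
    n_indel: int = 0,
    capture_mb: float = DEFAULT_CAPTURE_MB,
    seed: int = 0,
    chrom: str = "chr1",
    vaf: float = 0.45,
) -> tuple[list[MutationRecord], SimulationTruth]:
    """Somatic catalog whose SNV spectrum follows a known signature mixture.

    SNV channels are multinomial draws from catalog^T . exposures, each record
    carrying a consistent reference trinucleotide context (emitted on either
    strand at random) and filter metrics that pass all ten site filters.
    Indels are 1-bp insertions/deletions in homopolymer context.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (catalog.n_signatures,):
        raise ValueError("exposure vector length must match the catalog")
    if abs(exposures.sum() - 1.0) > 1e-6:
        raise ValueError("exposures must sum to 1")
    if n_snv < 0 or n_indel < 0:
        raise ValueError("counts must be non-negative")
    if capture_mb <= 0:
        raise ValueError("capture size must be positive")

    rng = np.random.default_rng(seed)
    probs = exposures @ catalog.matrix
    probs = probs / probs.sum()
    channel_counts = rng.multinomial(n_snv, probs) if n_snv else np.zeros(96, int)

    records: list[MutationRecord] = []
    pos = 1000
    for idx, count in enumerate(channel_counts):
        name = CHANNELS[idx]  # e.g. "A[C>T]G"
        five, ref, alt, three = name[0], name[2], name[4], name[6]
        for _ in range(count):
            context = five + ref + three
            r, a, ctx = ref, alt, context
            if rng.random() < 0.5:  # emit on the purine strand
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                r, a, ctx = comp[r], comp[a], reverse_complement(ctx)
            records.append(
                MutationRecord(
                    chrom, pos, r, a, "SNV", context=ctx,
                    **_passing_metrics(rng, a, vaf),
                )
            )
            pos += int(rng.integers(3, 50))
    for _ in range(n_indel):
        base = "ACGT"[rng.integers(4)]
        if rng.random() < 0.5:
            ref_allele, alt_allele, vclass = base, base + base, "insertion"
        else:
            ref_allele, alt_allele, vclass = base + base, base, "deletion"
        records.append(
            MutationRecord(
                chrom, pos, ref_allele, alt_allele, vclass,
                **_passing_metrics(rng, alt_allele, vaf),
            )
        )
        pos += int(rng.integers(3, 50))
    records.sort(key=lambda m: (m.chrom, m.pos))

    total = n_snv + n_indel
    truth = SimulationTruth(
        seed=seed,
        signature_exposures={
            sid: float(f) for sid, f in zip(catalog.ids, exposures)
        },
        indel_fraction=n_indel / total if total else 0.0,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def gen_msi_data(
    n_loci: int,
    instability_rate: float,
    mean_depth: float = 100.0,
    seed: int = 0,
) -> tuple[
    list[MicrosatelliteLocus],
    dict[str, RepeatLengthDistribution],
    dict[str, RepeatLengthDistribution],
    set[str],
]:
    """Locus panel plus tumor/normal repeat-length count tables.

    A fraction ``instability_rate`` of loci is made unstable in the tumor
    (polymorphism count exceeding mu + 3*sigma, every extra length passing the
    5%-of-max support rule); the normal sample is always stable.  Returns
    (loci, tumor distributions, normal distributions, unstable locus ids).
    """
    if not (0.0 <= instability_rate <= 1.0):
        raise ValueError("instability rate must lie in [0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    rng = np.random.default_rng(seed)

    loci: list[MicrosatelliteLocus] = []
    tumor: dict[str, RepeatLengthDistribution] = {}
    normal: dict[str, RepeatLengthDistribution] = {}
    unstable_ids: set[str] = set()

    for i in range(n_loci):
        locus_id = f"MS{i:05d}"
        mu = float(rng.uniform(1.0, 2.5))
        sigma = float(rng.uniform(0.2, 0.8))
        germline_len = int(rng.integers(10, 21))
        loci.append(
            MicrosatelliteLocus(
                locus_id,
                chrom=f"chr{int(rng.integers(1, 23))}",
                start=1000 * i,
                end=1000 * i + germline_len,
                repeat_unit="ACGT"[rng.integers(4)],
                background_mean=mu,
                background_sd=sigma,
            )
        )
        ceiling = math.floor(mu + 3.0 * sigma)
        is_unstable = rng.random() < instability_rate
        if is_unstable:
            unstable_ids.add(locus_id)
            k_tumor = math.ceil(mu + 3.0 * sigma) + 1 + int(rng.integers(0, 2))
        else:
            k_tumor = max(1, min(int(rng.integers(1, 3)), ceiling))
        k_normal = max(1, min(int(rng.integers(1, 3)), ceiling))

        tumor[locus_id] = _repeat_distribution(
            rng, locus_id, germline_len, k_tumor, mean_depth
        )
        normal[locus_id] = _repeat_distribution(
            rng, locus_id, germline_len, k_normal, mean_depth
        )
    return loci, tumor, normal, unstable_ids


def _repeat_distribution(
    rng: np.random.Generator,
    locus_id: str,
    germline_len: int,
    k: int,
    mean_depth: float,
) -> RepeatLengthDistribution:
    """Counts over ``k`` qualifying lengths, plus one sub-threshold noise length."""
    depth = int(rng.poisson(mean_depth))
    weights = np.concatenate([[1.0], rng.uniform(0.15, 0.35, size=k - 1)])
    raw = depth * weights / weights.sum()
    counts = np.maximum(np.round(raw).astype(int), 1) if depth > 0 else np.zeros(k, int)
    lengths = [germline_len] + [
        germline_len + d for d in _offsets(rng, k - 1)
    ]
    dist = {length: int(c) for length, c in zip(lengths, counts) if c > 0}
    if dist:
        noise = int(math.floor(0.05 * max(dist.values())))
        if noise > 0:  # at exactly the 5% boundary: must NOT be tallied
            dist[germline_len + 50] = noise
    return RepeatLengthDistribution(locus_id, dist)


def _offsets(rng: np.random.Generator, n: int) -> list[int]:
    pool = [d for d in range(-8, 9) if d != 0]
    return list(rng.choice(pool, size=n, replace=False)) if n else []


# ---------------------------------------------------------------------------
# Copy-number profiles
# ---------------------------------------------------------------------------

def gen_cnv_profile(
    segment_truth: Sequence[tuple[str, int, int, int, int]],
    purity_alpha: float,
    tumor_ploidy_target: Optional[float] = None,
    n_exons: int = 300,
    het_snp_rate: float = 2.0,
    noise_sd: float = 0.05,
    af_noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[list[ExonStat], SimulationTruth]:
    """Exon coverage/allele-fraction profile from a known (alpha, segments) truth.

    Each exon's relative coverage is drawn around
    (a*(A+B) + 2*(1-a)) / (a*tau + 2*(1-a)) and each heterozygous-SNP majority
    allele fraction around (a*A + (1-a)) / (a*(A+B) + 2*(1-a)), a = purity;
    tau is the length-weighted mean total copy number of the truth segments
    (``tumor_ploidy_target`` may assert it).  Majority fractions are folded at
    0.5, and the matched normal's fractions are folded draws around 0.5 with
    the same noise, so the downstream skew correction has real work to do.
    """
    if not (0.0 < purity_alpha <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    lengths = []
    for chrom, start, end, A, B in segment_truth:
        if not (A >= B >= 0) or (A, B) == (0, 0):
            raise ValueError(f"invalid allelic state ({A}, {B})")
        if end <= start:
            raise ValueError("segment end must exceed start")
        lengths.append(end - start)
    total_len = float(sum(lengths))
    tau = sum(
        (end - start) * (A + B) for chrom, start, end, A, B in segment_truth
    ) / total_len
    if tumor_ploidy_target is not None and abs(tau - tumor_ploidy_target) > 0.25:
        raise ValueError(
            f"segment truth implies ploidy {tau:.2f}, not {tumor_ploidy_target}"
        )

    rng = np.random.default_rng(seed)
    a = purity_alpha
    denom = a * tau + 2.0 * (1.0 - a)

    exons: list[ExonStat] = []
    for (chrom, start, end, A, B), seg_len in zip(segment_truth, lengths):
        k = max(1, round(n_exons * seg_len / total_len))
        bounds = np.linspace(start, end, k + 1).astype(int)
        copies = a * (A + B) + 2.0 * (1.0 - a)
        rc_exp = copies / denom
        af_exp = (a * A + (1.0 - a)) / copies
        for j in range(k):
            rc = max(float(rng.normal(rc_exp, noise_sd)), 0.0)
            exon = ExonStat(chrom, int(bounds[j]), int(bounds[j + 1]), rc, noise_sd)
            for _ in range(rng.poisson(het_snp_rate)):
                exon.af_t.append(_fold(rng.normal(af_exp, af_noise_sd)))
                exon.af_n.append(_fold(rng.normal(0.5, af_noise_sd)))
            exons.append(exon)

    truth = SimulationTruth(
        seed=seed,
        purity_alpha=purity_alpha,
        tumor_ploidy=float(tau),
        segment_truth=[tuple(s) for s in segment_truth],
    )
    return exons, truth


def _fold(x: float) -> float:
    return min(0.5 + abs(x - 0.5), 1.0)


#: Canonical benchmark genomes for purity/ploidy validation, one per target
#: ploidy.  Compositions keep no single aberrant state above half the genome:
#: median-centering of relative coverage assumes the genome-wide median sits
#: at (or near) the normal state, and a majority aberrant state would make the
#: low-purity problem fundamentally unidentifiable.
_MB = 1_000_000
BENCHMARK_GENOMES: dict[float, list[tuple[str, int, int, int, int]]] = {
    # 80% diploid + 20% single-allele loss
    1.8: [("chr1", 0, 40 * _MB, 1, 1), ("chr2", 0, 40 * _MB, 1, 1)]
    + [(f"chr{3 + i}", 0, 4 * _MB, 1, 0) for i in range(5)],
    # balanced gains and losses around a diploid genome
    2.0: [("chr1", 0, 40 * _MB, 1, 1), ("chr2", 0, 36 * _MB, 1, 1)]
    + [(f"chr{3 + i}", 0, 4 * _MB, 2, 1) for i in range(3)]
    + [(f"chr{6 + i}", 0, 4 * _MB, 1, 0) for i in range(3)],
    # widespread gain: 35% (2,2), 30% (2,1), 35% (1,1)
    3.0: [(f"chr{1 + i}", 0, 7 * _MB, 2, 2) for i in range(5)]
    + [(f"chr{6 + i}", 0, 6 * _MB, 2, 1) for i in range(5)]
    + [(f"chr{11 + i}", 0, 7 * _MB, 1, 1) for i in range(5)],
}


def benchmark_segment_truth(tau: float) -> list[tuple[str, int, int, int, int]]:
    """Benchmark segment list whose length-weighted mean copy number is tau."""
    try:
        return list(BENCHMARK_GENOMES[tau])
    except KeyError:
        raise ValueError(
            f"no benchmark genome for ploidy {tau}; available: "
            f"{sorted(BENCHMARK_GENOMES)}"
        ) from None


def gen_class_cohort(seed: int, capture_mb: float = DEFAULT_CAPTURE_MB):
    """One class-typical tumor profile per class, with its expected label.

    MSI: 40% mismatch-repair signature 6 plus 35% indels; UV: 60% signature 7
    at ~100 mutations/Mb; pauci-mutational: ~2/Mb dominated by the aging
    signature 1.  Signature exposures are re-fit from the simulated catalog
    (not copied from truth), so recovering the class exercises the whole
    spectrum -> NNLS -> rule-engine path.  Returns [(TumorProfile, label)].
    """
    from .classify import TumorProfile
    from .signatures import build_spectrum, fit_exposures, mutation_prevalence

    catalog = gen_signature_catalog(3, 0.05, seed=seed, ids=("1", "6", "7"))
    specs = [
        ("MSI", {"6": 0.4, "1": 0.6}, 650, 350),
        ("UV", {"7": 0.6, "1": 0.4}, 6252, 60),
        ("PAUCI", {"1": 1.0}, 120, 5),
    ]
    cohort = []
    for offset, (label, expo, n_snv, n_indel) in enumerate(specs):
        exposures = [expo.get(sid, 0.0) for sid in catalog.ids]
        records, _ = gen_mutation_catalog(
            catalog, exposures, n_snv, n_indel,
            capture_mb=capture_mb, seed=7919 * seed + offset,
        )
        profile = fit_exposures(build_spectrum(records), catalog)
        cohort.append(
            (
                TumorProfile(
                    sample_id=f"{label.lower()}_{seed}",
                    n_snv=n_snv,
                    n_indel=n_indel,
                    prevalence=mutation_prevalence(n_snv + n_indel, capture_mb),
                    exposures=profile,
                ),
                label,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Filter-engine fixtures
# ---------------------------------------------------------------------------

def gen_variant_records(
    n_sites: int,
    corruption_spec: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> list[MutationRecord]:
    """Variant records constructed to fail a known set of site filters.

    ``corruption_spec`` maps filter names to per-record corruption rates.
    Each record's ``truth_failed`` lists the filters it was built to fail; an
    empty label means the record passes all ten.  Physical consistency forces
    two interactions: a total depth below 4 (``dp``) caps the tumor alt depth
    below 4, so ``ad`` co-fails; and it also caps the normal alt depth, so a
    drawn ``gad`` or ``sb`` corruption is suppressed in favor of ``dp``
    (likewise ``ad`` suppresses ``sb``, whose biased strand pattern needs
    enough alt reads to reach significance).
    """
    spec = dict(corruption_spec or {})
    unknown = set(spec) - set(FILTER_NAMES)
    if unknown:
        raise ValueError(f"unknown filter name(s): {sorted(unknown)}")
    for name, rate in spec.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"corruption rate for {name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    records: list[MutationRecord] = []
    for i in range(n_sites):
        drawn = {name for name, rate in spec.items() if rng.random() < rate}
        label = set(drawn)

        if "dp" in drawn:
            label |= {"dp", "ad"}
            label -= {"gad", "sb"}
            depth_t, depth_n, alt_depth = 2, 1, 2
        elif "ad" in drawn:
            label -= {"sb"}
            depth_t, depth_n, alt_depth = 80, 60, 3
        else:
            depth_t, depth_n = 80, 60
            alt_depth = 12 if "sb" in drawn else 30

        if "sb" in label:
            fwd, rev = alt_depth, 0
        else:
            fwd, rev = alt_depth // 2, alt_depth - alt_depth // 2

        normal_alt = 5 if "gad" in label else 0
        alt = "T"
        support = {alt: alt_depth}
        if "ma" in drawn:
            support["G"] = 3

        records.append(
            MutationRecord(
                chrom="chr1",
                pos=100 + 10 * i,
                ref="C",
                alt=alt,
                variant_class="SNV",
                context="ACA",
                tumor_depth=depth_t,
                normal_depth=depth_n,
                tumor_alt_depth=alt_depth,
                normal_alt_depth=normal_alt,
                mq0_reads=6 if "mq0" in drawn else 0,
                alt_fwd=fwd,
                alt_rev=rev,
                mismatch_quality_sum=35.0 if "mmqs" in drawn else 5.0,
                avg_mismatches=2.5 if "amm" in drawn else 0.5,
                dist_to_3prime=(0.05 if rng.random() < 0.5 else 0.95)
                if "detp" in drawn
                else 0.5,
                somatic_score=10.0 if "conf" in drawn else 40.0,
                genotype_quality=10.0 if "conf" in drawn else 80.0,
                alt_allele_support=support,
                truth_failed=frozenset(label),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def gen_expression_matrix(
    n_genes: int,
    groups: Sequence[tuple[str, int]],
    effect_size: float = 2.0,
    seed: int = 0,
    marker_fraction: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """TPM-scale matrix with group-specific marker genes.

    Each group gets a disjoint marker set (``marker_fraction`` of genes split
    across groups) whose log2 expression is raised by ``effect_size`` in that
    group's samples; all other variation is independent noise, so with zero
    effect the sample-sample correlations center on zero.  Returns the
    genes-by-samples TPM table and a sample -> group label map.
    """
    if n_genes < 1 or not groups:
        raise ValueError("need at least one gene and one group")
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")
    rng = np.random.default_rng(seed)

    sample_ids, sample_group = [], {}
    for label, n_samples in groups:
        for j in range(n_samples):
            sid = f"{label}_{j}"
            sample_ids.append(sid)
            sample_group[sid] = label

    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_markers = int(marker_fraction * n_genes) // len(groups)
    marker_of: dict[str, slice] = {}
    for gi, (label, _) in enumerate(groups):
        marker_of[label] = slice(gi * n_markers, (gi + 1) * n_markers)

    log_expr = rng.normal(3.0, 1.0, size=(n_genes, len(sample_ids)))
    for si, sid in enumerate(sample_ids):
        log_expr[marker_of[sample_group[sid]], si] += effect_size
    tpm = np.power(2.0, log_expr)
    matrix = pd.DataFrame(tpm, index=genes, columns=sample_ids)
    return matrix, sample_group
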