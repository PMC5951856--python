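"""Core record types shared across the pipeline.

These are deliberately plain dataclasses: one somatic variant with the per-site
read metrics the filter engine consumes (:class:`MutationRecord`), microsatellite
loci and their repeat-length read-count distributions, exon-level coverage
statistics, merged copy-number segments, and the purity/ploidy solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class GenotypePairCall:
    """Joint tumor/normal genotype call.

    ``category`` is one of ``germline`` (identical genotypes), ``LOH`` (normal
    heterozygous, tumor homozygous), ``somatic`` (anything else) or ``hom_ref``.
    ``somatic_score`` is the Phred-scaled probability that tumor and normal
    genotypes are in fact equal, present only for somatic calls.
    """

    tumor_genotype: str
    normal_genotype: str
    category: str  # germline | LOH | somatic | hom_ref
    somatic_score: Optional[float] = None
    germline_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in {"germline", "LOH", "somatic", "hom_ref"}:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.somatic_score is not None) != (self.category == "somatic"):
            raise ValueError("somatic_score present iff category is somatic")


@dataclass
class MutationRecord:
    """One somatic variant plus the read-level metrics used by the site filters.

    Coordinates are 1-based.  ``variant_class`` is ``SNV``, ``insertion`` or
    ``deletion``; ``context`` is the reference trinucleotide around an SNV.
    Metrics left as ``None`` make the corresponding filter fail closed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # SNV | insertion | deletion
    context: Optional[str] = None
    tumor_depth: Optional[int] = None
    normal_depth: Optional[int] = None
    tumor_alt_depth: Optional[int] = None
    normal_alt_depth: Optional[int] = None
    mq0_reads: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    mismatch_quality_sum: Optional[float] = None  # per-read average quality sum
    avg_mismatches: Optional[float] = None        # per-read average mismatch count
    dist_to_3prime: Optional[float] = None        # mean fractional distance
    somatic_score: Optional[float] = None
    genotype_quality: Optional[float] = None
    alt_allele_support: Optional[dict[str, int]] = None
    genotype_call: Optional[GenotypePairCall] = None
    failed_filters: Optional[frozenset[str]] = None   # verdicts, once evaluated
    truth_failed: Optional[frozenset[str]] = None     # simulator label
    gene: Optional[str] = None
    consequence: Optional[str] = None
    origin: Optional[str] = None  # somatic | germline

    def __post_init__(self) -> None:
        if self.variant_class not in {"SNV", "insertion", "deletion"}:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if (
            self.tumor_alt_depth is not None
            and self.tumor_depth is not None
            and self.tumor_alt_depth > self.tumor_depth
        ):
            raise ValueError("tumor alt depth exceeds total depth")
        if (
            self.normal_alt_depth is not None
            and self.normal_depth is not None
            and self.normal_alt_depth > self.normal_depth
        ):
            raise ValueError("normal alt depth exceeds total depth")

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def is_indel(self) -> bool:
        return self.variant_class in {"insertion", "deletion"}

    @property
    def vaf(self) -> Optional[float]:
        if self.tumor_alt_depth is None or not self.tumor_depth:
            return None
        return self.tumor_alt_depth / self.tumor_depth


@dataclass
class MicrosatelliteLocus:
    """A homopolymer repeat locus with its background polymorphism model.

    ``background_mean``/``background_sd`` are the mean and standard deviation
    of the number of length polymorphisms observed at this locus across a large
    normal-sample panel.
    """

    locus_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    repeat_unit: str
    background_mean: float
    background_sd: float

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background sd must be non-negative")
        if self.end <= self.start:
            raise ValueError("end must exceed start")


@dataclass
class RepeatLengthDistribution:
    """Read support per observed repeat length at one microsatellite locus."""

    locus_id: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be non-negative")

    @property
    def total_depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class MsiCall:
    """Sample-level microsatellite-instability summary."""

    n_evaluated: int
    n_unstable_tumor: int
    percent_unstable_tumor: float
    n_evaluated_normal: Optional[int] = None
    n_unstable_normal: Optional[int] = None
    percent_unstable_normal: Optional[float] = None
    relative_percent: float = 0.0
    msi_high: bool = False


@dataclass
class ExonStat:
    """Per-exon coverage and majority-allele-fraction statistics.

    ``rc_mean``/``rc_sd`` summarize tumor/normal relative coverage across the
    positions of the exon; ``af_t``/``af_n`` hold one majority-allele-fraction
    value per heterozygous SNP.
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    rc_mean: float
    rc_sd: float
    af_t: list[float] = field(default_factory=list)
    af_n: list[float] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_het_snps(self) -> int:
        return len(self.af_t)


@dataclass
class AllelicState:
    """Integral allelic copy-number state (A majority, B minority copies)."""

    A: int
    B: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.A >= self.B >= 0) or (self.A, self.B) == (0, 0):
            raise ValueError(f"invalid allelic state ({self.A}, {self.B})")
        if self.clonal_fraction not in (0.5, 1.0):
            raise ValueError("clonal fraction must be 0.5 or 1.0")

    @property
    def total(self) -> int:
        return self.A + self.B

    def label(self) -> str:
        tag = "" if self.clonal_fraction == 1.0 else "/subclonal"
        return f"({self.A},{self.B}){tag}"


@dataclass
class Segment:
    """A merged run of exons with aggregated coverage and allele fractions."""

    chrom: str
    start: int
    end: int
    rc_mean: float
    rc_sd: float
    n_exons: int
    af_t: list[float] = field(default_factory=list)
    af_n: list[float] = field(default_factory=list)
    af_corr: Optional[float] = None
    state: Optional[AllelicState] = None
    deviation_p: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_het_snps(self) -> int:
        return len(self.af_t)


@dataclass
class PurityPloidyFit:
    """Best purity/ploidy solution across gradient-ascent restarts.

    ``alpha`` is the tumor-cell fraction of the specimen (1 - normal
    contamination); ``ploidy`` the segment-length-weighted mean tumor copy
    number recomputed from the best-fit parameters.
    """

    alpha: float
    ploidy: float
    log_likelihood: float
    n_restarts: int
    restarts: list[tuple[float, float, float]] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha outside [0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
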