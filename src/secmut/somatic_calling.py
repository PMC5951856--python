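"""Tumor/normal genotype-pair calling and the ten-rule somatic site filter.

The caller mirrors the classical paired-sample approach: per-sample diploid
genotype likelihoods from base and mapping qualities, a joint Bayesian model
over the 10 x 10 tumor/normal genotype pairs with a prior favoring the
reference and penalizing tumor/normal disagreement, and a Phred-scaled somatic
score SS = -10*log10 P(G_t = G_n | data) for sites whose most likely pair
differs.  Pairs with identical genotypes are germline; a heterozygous normal
with a homozygous tumor marks loss of heterozygosity (LOH).

Candidate somatic records then pass through ten named artifact filters
(``conf``, ``dp``, ``mq0``, ``sb``, ``mmqs``, ``amm``, ``detp``, ``ad``,
``gad``, ``ma``); a record passes only if every filter passes, and a missing
metric fails closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binomtest

from .records import GenotypePairCall, MutationRecord

BASES = "ACGT"
#: The 10 diploid genotypes in lexicographic order (AA, AC, ..., TT).
GENOTYPES: tuple[str, ...] = tuple(
    a + b for a, b in combinations_with_replacement(BASES, 2)
)

MIN_QUALIFYING_READS = 8
MIN_MAPPING_QUALITY = 20
_Q_FLOOR = 2.0   # epsilon floor, avoids log(0)
_Q_CAP = 60.0
MAX_PHRED = 255.0

FILTER_NAMES = ("conf", "dp", "mq0", "sb", "mmqs", "amm", "detp", "ad", "gad", "ma")


@dataclass
class Read:
    """One sequenced base observation at a pileup position."""

    base: str
    base_quality: float
    mapping_quality: float
    is_duplicate: bool = False
    strand: str = "+"
    dist_to_3prime: float = 0.5
    mismatches: int = 0
    mismatch_quality_sum: float = 0.0


@dataclass
class PileupSite:
    """Tumor and normal read pileups at one reference position."""

    chrom: str
    pos: int
    ref_base: str
    tumor_reads: list[Read] = field(default_factory=list)
    normal_reads: list[Read] = field(default_factory=list)


@dataclass
class PairPriors:
    """Priors of the joint genotype-pair model.

    ``het_rate`` is the fraction of heterozygous positions in the genome,
    split evenly over the three ref-containing heterozygotes.  ``somatic_rate``
    is the prior probability that the tumor genotype differs from the normal
    one, split evenly over the nine alternatives.  ``reference_prior`` defaults
    to the remaining mass after heterozygotes and the (small) non-reference
    homozygote/het-alt allowance.
    """

    het_rate: float = 1e-3
    somatic_rate: float = 1e-4
    reference_prior: Optional[float] = None
    nonref_rate: Optional[float] = None  # total mass on the 6 no-ref genotypes

    def normal_log_prior(self, ref_base: str) -> np.ndarray:
        nonref = self.nonref_rate if self.nonref_rate is not None else self.het_rate / 100
        ref_prior = (
            self.reference_prior
            if self.reference_prior is not None
            else 1.0 - self.het_rate - nonref
        )
        out = np.empty(len(GENOTYPES))
        for i, g in enumerate(GENOTYPES):
            if g == ref_base * 2:
                p = ref_prior
            elif ref_base in g:
                p = self.het_rate / 3.0
            else:
                p = nonref / 6.0
            out[i] = math.log(max(p, 1e-300))
        return out

    def transition_log_prior(self) -> np.ndarray:
        same = math.log(max(1.0 - self.somatic_rate, 1e-300))
        diff = math.log(max(self.somatic_rate / 9.0, 1e-300))
        n = len(GENOTYPES)
        out = np.full((n, n), diff)
        np.fill_diagonal(out, same)
        return out


def _qualifying(reads: Sequence[Read]) -> list[Read]:
    return [
        r
        for r in reads
        if not r.is_duplicate and r.mapping_quality >= MIN_MAPPING_QUALITY
    ]


def genotype_likelihoods(reads: Sequence[Read]) -> Optional[np.ndarray]:
    """Log-likelihood of each diploid genotype from a read pileup.

    Only non-duplicate reads with mapping quality >= 20 are used; returns
    ``None`` (site-skipped signal) when fewer than 8 qualify.  Per read the
    error rate is eps = 10**(-min(base quality, mapping quality)/10), clamped
    to [Q2, Q60]; a genotype {a1, a2} assigns the read probability
    0.5*p(base|a1) + 0.5*p(base|a2) with p = 1-eps on a match, eps/3 otherwise.
    """
    usable = _qualifying(reads)
    if len(usable) < MIN_QUALIFYING_READS:
        return None
    lls = np.zeros(len(GENOTYPES))
    for r in usable:
        q = min(r.base_quality, r.mapping_quality)
        q = min(max(q, _Q_FLOOR), _Q_CAP)
        eps = 10.0 ** (-q / 10.0)
        p_match, p_mismatch = 1.0 - eps, eps / 3.0
        for i, g in enumerate(GENOTYPES):
            p1 = p_match if r.base == g[0] else p_mismatch
            p2 = p_match if r.base == g[1] else p_mismatch
            lls[i] += math.log(0.5 * p1 + 0.5 * p2)
    return lls


def _phred(p: float) -> float:
    if p <= 0.0:
        return MAX_PHRED
    return min(MAX_PHRED, -10.0 * math.log10(p))


def classify_genotype_pair(
    tumor_lls: np.ndarray,
    normal_lls: np.ndarray,
    ref_base: str,
    priors: Optional[PairPriors] = None,
) -> GenotypePairCall:
    """Pick the most likely tumor/normal genotype pair and categorize it.

    The joint posterior over the 100 pairs combines the normal-genotype prior,
    the tumor-given-normal transition prior and both likelihood vectors.  Ties
    in the argmax are broken toward genotypes containing the reference allele.
    """
    priors = priors or PairPriors()
    tumor_lls = np.asarray(tumor_lls, dtype=float)
    normal_lls = np.asarray(normal_lls, dtype=float)
    if not (np.all(np.isfinite(tumor_lls)) and np.all(np.isfinite(normal_lls))):
        raise ValueError("genotype likelihoods must be finite")

    log_joint = (
        priors.normal_log_prior(ref_base)[:, None]
        + priors.transition_log_prior()
        + normal_lls[:, None]
        + tumor_lls[None, :]
    )
    log_post = log_joint - logsumexp(log_joint)
    post = np.exp(log_post)

    # argmax with ref-containing genotypes preferred on ties
    order = sorted(
        range(len(GENOTYPES)),
        key=lambda i: (ref_base not in GENOTYPES[i], GENOTYPES[i]),
    )
    best_n, best_t, best = 0, 0, -math.inf
    for i in order:
        for j in order:
            if log_post[i, j] > best + 1e-12:
                best, best_n, best_t = log_post[i, j], i, j

    g_n, g_t = GENOTYPES[best_n], GENOTYPES[best_t]
    hom_ref = ref_base * 2
    p_equal = float(np.trace(post))

    if g_n == g_t:
        category = "hom_ref" if g_n == hom_ref else "germline"
        quality = _phred(max(1.0 - float(post[best_n, best_t]), 0.0))
        return GenotypePairCall(g_t, g_n, category, germline_quality=quality)
    normal_het = g_n[0] != g_n[1]
    tumor_hom = g_t[0] == g_t[1]
    if normal_het and tumor_hom:
        quality = _phred(max(1.0 - float(post[best_n, best_t]), 0.0))
        return GenotypePairCall(g_t, g_n, "LOH", germline_quality=quality)
    return GenotypePairCall(g_t, g_n, "somatic", somatic_score=_phred(p_equal))


def call_site(
    site: PileupSite, priors: Optional[PairPriors] = None
) -> Optional[GenotypePairCall]:
    """Full per-site calling: depth gate, hom-ref shortcut, pair classification.

    Returns ``None`` when either sample has fewer than 8 qualifying reads.
    Sites with fewer than two reads supporting any non-reference allele are
    deemed homozygous reference without running the pair model.
    """
    t_lls = genotype_likelihoods(site.tumor_reads)
    n_lls = genotype_likelihoods(site.normal_reads)
    if t_lls is None or n_lls is None:
        return None
    nonref = sum(
        1
        for r in _qualifying(site.tumor_reads) + _qualifying(site.normal_reads)
        if r.base != site.ref_base
    )
    if nonref < 2:
        g = site.ref_base * 2
        return GenotypePairCall(g, g, "hom_ref", germline_quality=MAX_PHRED)
    return classify_genotype_pair(t_lls, n_lls, site.ref_base, priors)


# ---------------------------------------------------------------------------
# The ten site filters
# ---------------------------------------------------------------------------

SB_P_THRESHOLD = 0.005
CONF_MIN = 15.0
DP_MIN = 4
MQ0_MAX = 4          # pass iff MQ0 reads < 5
MMQS_MAX = 20.0
AMM_MAX = 1.5
DETP_LOW, DETP_HIGH = 0.2, 0.8
AD_MIN = 4
GAD_MAX = 3


def strand_bias_pvalue(alt_fwd: int, alt_rev: int) -> float:
    """Two-sided exact binomial p-value for forward/reverse alt-read balance."""
    n = alt_fwd + alt_rev
    if n == 0:
        return 1.0
    return binomtest(alt_fwd, n, 0.5).pvalue


def _filter_conf(r: MutationRecord) -> Optional[bool]:
    if r.genotype_quality is None and r.somatic_score is None:
        return None
    candidates = [v for v in (r.genotype_quality, r.somatic_score) if v is not None]
    return any(v >= CONF_MIN for v in candidates)


def _filter_dp(r: MutationRecord) -> Optional[bool]:
    if r.tumor_depth is None or r.normal_depth is None:
        return None
    return r.tumor_depth + r.normal_depth >= DP_MIN


def _filter_mq0(r: MutationRecord) -> Optional[bool]:
    if r.mq0_reads is None:
        return None
    return r.mq0_reads <= MQ0_MAX


def _filter_sb(r: MutationRecord) -> Optional[bool]:
    if r.alt_fwd is None or r.alt_rev is None:
        return None
    return strand_bias_pvalue(r.alt_fwd, r.alt_rev) > SB_P_THRESHOLD


def _filter_mmqs(r: MutationRecord) -> Optional[bool]:
    if r.mismatch_quality_sum is None:
        return None
    return r.mismatch_quality_sum <= MMQS_MAX


def _filter_amm(r: MutationRecord) -> Optional[bool]:
    if r.avg_mismatches is None:
        return None
    return r.avg_mismatches <= AMM_MAX


def _filter_detp(r: MutationRecord) -> Optional[bool]:
    # variants clustered at read ends are artifacts: reject <0.2 or >0.8
    if r.dist_to_3prime is None:
        return None
    return DETP_LOW <= r.dist_to_3prime <= DETP_HIGH


def _filter_ad(r: MutationRecord) -> Optional[bool]:
    if r.tumor_alt_depth is None:
        return None
    return r.tumor_alt_depth >= AD_MIN


def _filter_gad(r: MutationRecord) -> Optional[bool]:
    if r.normal_alt_depth is None:
        return None
    return r.normal_alt_depth <= GAD_MAX


def _filter_ma(r: MutationRecord) -> Optional[bool]:
    # reject when >=2 reads support two or more alternate alleles
    if r.alt_allele_support is None:
        return None
    strong = sum(1 for c in r.alt_allele_support.values() if c >= 2)
    return strong < 2


_FILTERS = {
    "conf": _filter_conf,
    "dp": _filter_dp,
    "mq0": _filter_mq0,
    "sb": _filter_sb,
    "mmqs": _filter_mmqs,
    "amm": _filter_amm,
    "detp": _filter_detp,
    "ad": _filter_ad,
    "gad": _filter_gad,
    "ma": _filter_ma,
}
assert tuple(_FILTERS) == FILTER_NAMES


def apply_site_filters(record: MutationRecord) -> tuple[bool, frozenset[str]]:
    """Evaluate the ten site filters; returns (passed, failed-filter names).

    A filter whose input metric is missing is recorded as failed (fail closed).
    The failed set is also stored on ``record.failed_filters``.
    """
    def _passes(verdict: Optional[bool]) -> bool:
        return verdict is not None and bool(verdict)

    failed = frozenset(
        name for name, fn in _FILTERS.items() if not _passes(fn(record))
    )
    record.failed_filters = failed
    return (len(failed) == 0, failed)
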