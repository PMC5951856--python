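"""Allele-specific copy number: exon statistics, segmentation, purity/ploidy.

The copy-number proxy is per-exon relative coverage RC = DP^t/DP^n, paired
with the majority allele fraction AF_m at heterozygous germline SNPs.  Exons
are merged into segments over three agglomerative rounds (neighbors merge when
a two-sample t-test cannot distinguish them), RC is centered so the
genome-wide median is 1.0, and tumor-vs-normal sampling skew in AF_m is
corrected by

    AF_corr = AF_t - (AF_n - 0.5) * exp(-0.5*((AF_t - AF_n)/0.05)^2)

which subtracts the normal's skew only where tumor and normal fractions agree
(balanced regions).  Tumor purity alpha and ploidy tau are then fit by
multi-restart projected gradient ascent of a segment-length-weighted Gaussian
log-likelihood in which each segment is explained by its best allelic state
(A, B) from a fixed set of common states, with expected values

    RC(A,B)  = (a*(A+B) + 2*(1-a)) / (a*tau + 2*(1-a))
    AF(A,B)  = (a*A + (1-a)) / (a*(A+B) + 2*(1-a)),   a = alpha*clonal_fraction

the standard two-population (tumor + contaminating normal) mixture model.
Final ploidy is recomputed as the length-weighted mean tumor copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .records import AllelicState, ExonStat, PurityPloidyFit, Segment

MIN_EXON_DEPTH = 5
SNP_MIN_DP_T = 10
SNP_MIN_DP_N = 20
HET_AF_LOW, HET_AF_HIGH = 0.25, 0.75
MERGE_P = 0.95
N_ROUNDS = 3
DEVIATION_P = 0.05
REPORT_MIN_BP = 2_500_000

#: Common allelic states: normal, single-copy gain, LOH, copy-neutral LOH and
#: balanced amplification, plus 50/50 subclonal mixtures of each altered state
#: with the normal (1,1) state.
DEFAULT_STATES: tuple[AllelicState, ...] = (
    AllelicState(1, 1),
    AllelicState(2, 1),
    AllelicState(1, 0),
    AllelicState(2, 0),
    AllelicState(2, 2),
    AllelicState(2, 1, 0.5),
    AllelicState(1, 0, 0.5),
    AllelicState(2, 0, 0.5),
    AllelicState(2, 2, 0.5),
)

AUTOSOMES = {str(i) for i in range(1, 23)}


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") in AUTOSOMES


# ---------------------------------------------------------------------------
# Exon statistics
# ---------------------------------------------------------------------------

def compute_exon_stats(
    exon_table: pd.DataFrame, snp_table: Optional[pd.DataFrame] = None
) -> list[ExonStat]:
    """Exon-level RC and heterozygous-SNP majority allele fractions.

    ``exon_table`` needs columns chrom/start/end/depth_t/depth_n (mean depths;
    0-based half-open intervals) and optionally rc_sd; without rc_sd a
    Poisson-propagation estimate RC*sqrt(1/DP_t + 1/DP_n) is used.
    ``snp_table`` needs chrom/pos/ref_t/alt_t/ref_n/alt_n allele read counts.

    Exons with average depth < 5 in both tumor and normal are removed; SNPs
    require DP_t >= 10, DP_n >= 20 and a normal allele fraction in
    [0.25, 0.75] to count as heterozygous.
    """
    stats_out: list[ExonStat] = []
    snps_by_chrom: dict[str, pd.DataFrame] = {}
    if snp_table is not None and len(snp_table):
        for chrom, grp in snp_table.groupby("chrom"):
            snps_by_chrom[str(chrom)] = grp.sort_values("pos").reset_index(drop=True)

    for row in exon_table.itertuples(index=False):
        depth_t, depth_n = float(row.depth_t), float(row.depth_n)
        if depth_t < MIN_EXON_DEPTH and depth_n < MIN_EXON_DEPTH:
            continue
        if depth_n <= 0:
            continue
        rc = depth_t / depth_n
        rc_sd = float(getattr(row, "rc_sd", float("nan")))
        if math.isnan(rc_sd):
            rc_sd = rc * math.sqrt(1.0 / max(depth_t, 1.0) + 1.0 / depth_n)
        exon = ExonStat(str(row.chrom), int(row.start), int(row.end), rc, rc_sd)

        grp = snps_by_chrom.get(exon.chrom)
        if grp is not None:
            sel = grp[(grp.pos >= exon.start) & (grp.pos < exon.end)]
            for snp in sel.itertuples(index=False):
                dp_t = snp.ref_t + snp.alt_t
                dp_n = snp.ref_n + snp.alt_n
                if dp_t < SNP_MIN_DP_T or dp_n < SNP_MIN_DP_N:
                    continue
                af_n_alt = snp.alt_n / dp_n
                if not (HET_AF_LOW <= af_n_alt <= HET_AF_HIGH):
                    continue
                exon.af_t.append(max(snp.ref_t, snp.alt_t) / dp_t)
                exon.af_n.append(max(snp.ref_n, snp.alt_n) / dp_n)
        stats_out.append(exon)
    return stats_out


# ---------------------------------------------------------------------------
# Agglomerative segmentation
# ---------------------------------------------------------------------------

def welch_p_from_stats(
    m1: float, s1: float, n1: float, m2: float, s2: float, n2: float
) -> float:
    """Two-sided Welch t-test p-value from summary statistics."""
    v1 = (s1 * s1) / n1
    v2 = (s2 * s2) / n2
    se2 = v1 + v2
    if se2 <= 0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(se2)
    den = 0.0
    if n1 > 1:
        den += v1 * v1 / (n1 - 1)
    if n2 > 1:
        den += v2 * v2 / (n2 - 1)
    df = se2 * se2 / den if den > 0 else max(n1 + n2 - 2, 1)
    return float(2.0 * stats.t.sf(abs(t), df))


def _af_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    return float(arr.mean()), sd


def _segments_mergeable(a: Segment, b: Segment, merge_p: float) -> bool:
    p_rc = welch_p_from_stats(
        a.rc_mean, a.rc_sd, a.length, b.rc_mean, b.rc_sd, b.length
    )
    if p_rc <= merge_p:
        return False
    if a.n_het_snps and b.n_het_snps:
        ma, sa = _af_mean_sd(a.af_t)
        mb, sb = _af_mean_sd(b.af_t)
        p_af = welch_p_from_stats(ma, sa, a.n_het_snps, mb, sb, b.n_het_snps)
        if p_af <= merge_p:
            return False
    return True


def _merge_pair(a: Segment, b: Segment) -> Segment:
    # base-pair-weighted pooling of the position-level RC moments
    na, nb = a.length, b.length
    mean = (na * a.rc_mean + nb * b.rc_mean) / (na + nb)
    second = (
        na * (a.rc_sd**2 + a.rc_mean**2) + nb * (b.rc_sd**2 + b.rc_mean**2)
    ) / (na + nb)
    sd = math.sqrt(max(second - mean * mean, 0.0))
    return Segment(
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        rc_mean=mean,
        rc_sd=sd,
        n_exons=a.n_exons + b.n_exons,
        af_t=a.af_t + b.af_t,
        af_n=a.af_n + b.af_n,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(v[min(idx, len(v) - 1)])


def agglomerate_segments(
    exon_stats: Sequence[ExonStat],
    n_rounds: int = N_ROUNDS,
    merge_p: float = MERGE_P,
    center: bool = True,
) -> list[Segment]:
    """Merge adjacent exons into segments over ``n_rounds`` agglomerative rounds.

    Within each round a single left-to-right pass merges each pair of
    neighboring units that do not differ significantly in RC (and in tumor
    majority allele fraction, when both carry het SNPs); a unit merges at most
    once per round.  Afterwards RC is rescaled so the base-pair-weighted
    genome-wide median is exactly 1.0.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for e in sorted(exon_stats, key=lambda e: (e.chrom, e.start)):
        by_chrom.setdefault(e.chrom, []).append(
            Segment(
                e.chrom, e.start, e.end, e.rc_mean, e.rc_sd,
                n_exons=1, af_t=list(e.af_t), af_n=list(e.af_n),
            )
        )

    for _ in range(n_rounds):
        for chrom, segs in by_chrom.items():
            merged: list[Segment] = []
            i = 0
            while i < len(segs):
                if i + 1 < len(segs) and _segments_mergeable(
                    segs[i], segs[i + 1], merge_p
                ):
                    merged.append(_merge_pair(segs[i], segs[i + 1]))
                    i += 2
                else:
                    merged.append(segs[i])
                    i += 1
            by_chrom[chrom] = merged

    segments = [s for segs in by_chrom.values() for s in segs]
    segments.sort(key=lambda s: (s.chrom, s.start))
    if center and segments:
        rc = np.array([s.rc_mean for s in segments])
        w = np.array([s.length for s in segments], dtype=float)
        med = _weighted_median(rc, w)
        if med > 0:
            for s in segments:
                s.rc_mean /= med
                s.rc_sd /= med
    return segments


# ---------------------------------------------------------------------------
# Allele-fraction correction
# ---------------------------------------------------------------------------

def correct_majority_af(af_t: float, af_n: float) -> float:
    """Remove normal-sample sampling skew from the tumor majority AF.

    Exact evaluation of
    AF_corr = AF_t - (AF_n - 0.5)*exp(-0.5*((AF_t - AF_n)/0.05)^2),
    clamped back into [0.5, 1].
    """
    if not (0.0 <= af_t <= 1.0 and 0.0 <= af_n <= 1.0):
        raise ValueError("allele fractions must lie in [0, 1]")
    corr = af_t - (af_n - 0.5) * math.exp(-0.5 * ((af_t - af_n) / 0.05) ** 2)
    return min(max(corr, 0.5), 1.0)


# ---------------------------------------------------------------------------
# Purity / ploidy fitting
# ---------------------------------------------------------------------------

def expected_rc(state: AllelicState, alpha: float, tau: float) -> float:
    a = alpha * state.clonal_fraction
    return (a * state.total + 2.0 * (1.0 - a)) / (a * tau + 2.0 * (1.0 - a))


def expected_af(state: AllelicState, alpha: float) -> float:
    a = alpha * state.clonal_fraction
    return (a * state.A + (1.0 - a)) / (a * state.total + 2.0 * (1.0 - a))


@dataclass
class _SegmentArrays:
    rc: np.ndarray
    rc_sd: np.ndarray
    af: np.ndarray       # corrected AF; NaN where unavailable
    af_sd: np.ndarray
    af_n_bias: np.ndarray  # normal-sample majority-fold bias, mean(AF_n) - 0.5
    w: np.ndarray        # normalized bp weights
    segments: list[Segment]


def _expected_corrected_af(
    af_exp: np.ndarray, af_n_bias: np.ndarray
) -> np.ndarray:
    """Push model AF expectations through the observation process.

    Observed majority fractions are folded at 0.5, which inflates them by a
    bias that the matched normal shares (its own folded mean is 0.5 + b); the
    skew correction then subtracts that bias through a Gaussian gate of width
    0.05.  Near-balanced states would otherwise appear biased, and weakly
    imbalanced states (low purity) would have part of their true signal
    subtracted, so the same folding + correction is applied to the expected
    values before comparison: like is compared with like.

    ``af_exp``: (n_states,) model expectations; ``af_n_bias``: (n_segments,)
    per-segment fold bias b = mean(AF_n) - 0.5.  Returns (n_segments,
    n_states).  The per-SNP noise scale is recovered from b via the half-
    normal mean relation sigma = b * sqrt(pi/2).
    """
    from scipy.special import ndtr

    b = np.maximum(af_n_bias, 1e-6)[:, None]
    sigma = b * math.sqrt(math.pi / 2.0)
    d = (af_exp - 0.5)[None, :]
    z = d / sigma
    # E|X - 0.5| for X ~ N(0.5 + d, sigma^2)
    fold_mean = d * (1.0 - 2.0 * ndtr(-z)) + 2.0 * sigma * np.exp(
        -0.5 * z * z
    ) / math.sqrt(2.0 * math.pi)
    af_obs = 0.5 + fold_mean
    gate = np.exp(-0.5 * ((af_obs - (0.5 + b)) / 0.05) ** 2)
    return af_obs - b * gate


class PurityPloidyEstimator(BaseEstimator):
    """Purity/ploidy fit by multi-restart projected gradient ascent.

    Parameters
    ----------
    states : sequence of AllelicState, optional
        Candidate allelic states (default :data:`DEFAULT_STATES`).
    n_restarts : int
        Number of random initializations (minimum, and default, 10).
    random_state : int or None
        Seed for the restart initializations.
    rc_sd_floor, af_sd_floor : float
        Lower bounds on segment standard deviations entering the Gaussian
        likelihood, guarding against degenerate zero-variance segments.
    subclonal_penalty : float
        Per-segment log-likelihood penalty on subclonal state assignments.
        It breaks the exact (alpha, clonal) vs (2*alpha, 50/50-subclonal)
        likelihood tie in favor of the parsimonious clonal explanation, and
        stops densely packed subclonal expectations from chasing per-segment
        noise at low purity.
    non_normal_penalty : float
        Per-segment log-likelihood penalty on any state other than the normal
        (1,1): a parsimony prior favoring the explanation that aberrates the
        least genome.  It resolves the whole-genome-doubling degeneracy
        ((1,1)->(2,2), (1,0)->(2,0) at doubled ploidy is otherwise likelihood-
        equivalent) toward the near-diploid solution.
    degeneracy_gain : float
        Minimum log-likelihood gain (per unit of genome weight) of the best
        fit over a forced all-(1,1) diploid null for purity to be considered
        identifiable; below it the fit is flagged degenerate, as is any fit
        whose near-tied restarts disagree on alpha by more than 0.2.

    Attributes
    ----------
    alpha_ : float
        Tumor-cell fraction at the optimum.
    ploidy_ : float
        Length-weighted mean tumor copy number recomputed from the fit.
    tau_opt_ : float
        The ploidy parameter at the likelihood optimum.
    loglik_ : float
        Best joint log-likelihood across restarts.
    fit_result_ : PurityPloidyFit
    """

    ALPHA_BOUNDS = (0.05, 1.0)
    TAU_BOUNDS = (1.0, 8.0)

    def __init__(
        self,
        states: Optional[Sequence[AllelicState]] = None,
        n_restarts: int = 10,
        random_state: Optional[int] = None,
        rc_sd_floor: float = 0.02,
        af_sd_floor: float = 0.02,
        subclonal_penalty: float = 0.5,
        non_normal_penalty: float = 1.0,
        degeneracy_gain: float = 1.0,
        autosomes_only: bool = True,
    ):
        self.states = states
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.rc_sd_floor = rc_sd_floor
        self.af_sd_floor = af_sd_floor
        self.subclonal_penalty = subclonal_penalty
        self.non_normal_penalty = non_normal_penalty
        self.degeneracy_gain = degeneracy_gain
        self.autosomes_only = autosomes_only

    # -- likelihood machinery ------------------------------------------------

    def _prepare(self, segments: Sequence[Segment]) -> _SegmentArrays:
        segs = [s for s in segments if not self.autosomes_only or _is_autosome(s.chrom)]
        if not segs:
            segs = list(segments)  # non-standard chromosome names: use all
        rc = np.array([s.rc_mean for s in segs])
        rc_sd = np.maximum([s.rc_sd for s in segs], self.rc_sd_floor)
        af = np.full(len(segs), np.nan)
        af_sd = np.full(len(segs), self.af_sd_floor)
        af_n_bias = np.zeros(len(segs))
        for i, s in enumerate(segs):
            if s.n_het_snps >= 3:
                m_t, sd_t = _af_mean_sd(s.af_t)
                m_n, _ = _af_mean_sd(s.af_n)
                s.af_corr = correct_majority_af(m_t, m_n)
                af[i] = s.af_corr
                af_sd[i] = max(sd_t, self.af_sd_floor)
                af_n_bias[i] = max(m_n - 0.5, 0.0)
        if np.all(np.isnan(af)):
            raise ValueError(
                "no segments carry allele-fraction information (>=3 het SNPs); "
                "purity is unidentifiable -- consider a coverage-only analysis"
            )
        w = np.array([s.length for s in segs], dtype=float)
        return _SegmentArrays(rc, rc_sd, af, af_sd, af_n_bias, w / w.sum(), segs)

    def _state_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cached = getattr(self, "_state_cache", None)
        if cached is not None:
            return cached
        states = tuple(self.states) if self.states is not None else DEFAULT_STATES
        A = np.array([s.A for s in states], dtype=float)
        total = np.array([s.total for s in states], dtype=float)
        cf = np.array([s.clonal_fraction for s in states])
        self._state_cache = (A, total, cf)
        return self._state_cache

    def _loglik(self, arrays: _SegmentArrays, alpha: float, tau: float) -> float:
        return float(np.dot(arrays.w, self._segment_ll(arrays, alpha, tau)[0]))

    def _segment_ll(
        self, arrays: _SegmentArrays, alpha: float, tau: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-segment best-state log-likelihood and argmax state index."""
        A, total, cf = self._state_arrays()
        a = alpha * cf
        denom_rc = a * tau + 2.0 * (1.0 - a)
        copies = a * total + 2.0 * (1.0 - a)
        rc_exp = copies / denom_rc                       # (n_states,)
        af_exp = (a * A + (1.0 - a)) / copies

        log_sqrt_2pi = 0.9189385332046727
        z_rc = (arrays.rc[:, None] - rc_exp[None, :]) / arrays.rc_sd[:, None]
        rc_term = -0.5 * z_rc * z_rc - np.log(arrays.rc_sd)[:, None] - log_sqrt_2pi
        has_af = ~np.isnan(arrays.af)
        af_term = np.zeros_like(rc_term)
        if has_af.any():
            af_exp_corr = _expected_corrected_af(
                af_exp, arrays.af_n_bias[has_af]
            )
            z_af = (
                arrays.af[has_af, None] - af_exp_corr
            ) / arrays.af_sd[has_af, None]
            af_term[has_af] = (
                -0.5 * z_af * z_af - np.log(arrays.af_sd[has_af])[:, None] - log_sqrt_2pi
            )
        is_normal = (A == 1.0) & (total == 2.0) & (cf == 1.0)
        penalty = (
            self.subclonal_penalty * (cf < 1.0)
            + self.non_normal_penalty * ~is_normal
        )
        ll = rc_term + af_term - penalty[None, :]
        best = np.argmax(ll, axis=1)
        return ll[np.arange(ll.shape[0]), best], best

    # -- optimizer -----------------------------------------------------------

    def _ascend(
        self, arrays: _SegmentArrays, alpha0: float, tau0: float
    ) -> tuple[float, float, float]:
        lo = np.array([self.ALPHA_BOUNDS[0], self.TAU_BOUNDS[0]])
        hi = np.array([self.ALPHA_BOUNDS[1], self.TAU_BOUNDS[1]])
        x = np.clip(np.array([alpha0, tau0]), lo, hi)
        f = self._loglik(arrays, *x)
        step = 0.2
        h = np.array([1e-4, 1e-3])
        for _ in range(300):
            grad = np.empty(2)
            for k in range(2):
                xp, xm = x.copy(), x.copy()
                xp[k] = min(x[k] + h[k], hi[k])
                xm[k] = max(x[k] - h[k], lo[k])
                span = xp[k] - xm[k]
                grad[k] = (
                    (self._loglik(arrays, *xp) - self._loglik(arrays, *xm)) / span
                    if span > 0
                    else 0.0
                )
            norm = np.linalg.norm(grad)
            if norm == 0:
                break
            improved = False
            while step > 1e-7:
                cand = np.clip(x + step * grad / norm, lo, hi)
                fc = self._loglik(arrays, *cand)
                if fc > f:
                    gain = fc - f
                    x, f = cand, fc
                    step = min(step * 1.5, 0.5)
                    improved = True
                    if gain < 1e-6:
                        return float(x[0]), float(x[1]), f
                    break
                step *= 0.5  # halve until an uphill step is found
            if not improved:
                break
        return float(x[0]), float(x[1]), f

    def fit(self, segments: Sequence[Segment], y=None) -> "PurityPloidyEstimator":
        self._state_cache = None
        arrays = self._prepare(segments)
        rng = np.random.default_rng(self.random_state)
        n_restarts = max(self.n_restarts, 10)
        restarts: list[tuple[float, float, float]] = []
        for _ in range(n_restarts):
            a0 = rng.uniform(*self.ALPHA_BOUNDS)
            t0 = rng.uniform(*self.TAU_BOUNDS)
            restarts.append(self._ascend(arrays, a0, t0))
        best_alpha, best_tau, best_ll = max(restarts, key=lambda r: r[2])

        # degenerate when near-tied restarts disagree on alpha, or when the fit
        # barely improves on a diploid genome with no aberration at all
        near = [r for r in restarts if r[2] >= best_ll - max(1e-3, 1e-4 * abs(best_ll))]
        alpha_scatter = (max(r[0] for r in near) - min(r[0] for r in near)) > 0.2
        degenerate = alpha_scatter or (
            best_ll - self._null_loglik(arrays) < self.degeneracy_gain
        )

        self.alpha_ = best_alpha
        self.tau_opt_ = best_tau
        self.loglik_ = best_ll
        self.ploidy_ = self._recompute_ploidy(arrays, best_alpha, best_tau)
        self.arrays_ = arrays
        self.fit_result_ = PurityPloidyFit(
            alpha=best_alpha,
            ploidy=self.ploidy_,
            log_likelihood=best_ll,
            n_restarts=n_restarts,
            restarts=restarts,
            degenerate=degenerate,
        )
        return self

    def _null_loglik(self, arrays: _SegmentArrays) -> float:
        """Log-likelihood of a diploid genome: every segment (1,1), RC 1, AF 0.5."""
        log_sqrt_2pi = 0.9189385332046727
        z_rc = (arrays.rc - 1.0) / arrays.rc_sd
        ll = -0.5 * z_rc * z_rc - np.log(arrays.rc_sd) - log_sqrt_2pi
        has_af = ~np.isnan(arrays.af)
        z_af = (arrays.af[has_af] - 0.5) / arrays.af_sd[has_af]
        af_ll = -0.5 * z_af * z_af - np.log(arrays.af_sd[has_af]) - log_sqrt_2pi
        ll = ll.copy()
        ll[has_af] += af_ll
        return float(np.dot(arrays.w, ll))

    def _recompute_ploidy(
        self, arrays: _SegmentArrays, alpha: float, tau: float
    ) -> float:
        """Length-weighted mean tumor copy number implied by the RC profile."""
        denom = alpha * tau + 2.0 * (1.0 - alpha)
        cn = (arrays.rc * denom - 2.0 * (1.0 - alpha)) / alpha
        return float(np.dot(arrays.w, np.maximum(cn, 0.0)))


def fit_purity_ploidy(
    segments: Sequence[Segment],
    states: Optional[Sequence[AllelicState]] = None,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> PurityPloidyFit:
    """Functional wrapper over :class:`PurityPloidyEstimator`."""
    est = PurityPloidyEstimator(
        states=states, n_restarts=n_restarts, random_state=seed
    ).fit(segments)
    return est.fit_result_


# ---------------------------------------------------------------------------
# State assignment
# ---------------------------------------------------------------------------

def _deviation_p(
    seg: Segment, state: AllelicState, alpha: float, tau: float
) -> float:
    """t-test p-value of the segment's RC (and AF) against one integral state."""
    rc_exp = expected_rc(state, alpha, tau)
    n = max(seg.n_exons, 1)
    if n >= 2 and seg.rc_sd > 0:
        t = (seg.rc_mean - rc_exp) / (seg.rc_sd / math.sqrt(n))
        p_rc = float(2.0 * stats.t.sf(abs(t), n - 1))
    else:
        sd = max(seg.rc_sd, 1e-6)
        p_rc = float(2.0 * stats.norm.sf(abs(seg.rc_mean - rc_exp) / sd))
    p = p_rc
    if seg.af_corr is not None and seg.n_het_snps >= 3:
        _, sd_af = _af_mean_sd(seg.af_t)
        sd_af = max(sd_af, 1e-6)
        af_exp = expected_af(state, alpha)
        t_af = (seg.af_corr - af_exp) / (sd_af / math.sqrt(seg.n_het_snps))
        p_af = float(2.0 * stats.t.sf(abs(t_af), seg.n_het_snps - 1))
        p = min(p, p_af)
    return p


def assign_allelic_states(
    segments: Sequence[Segment],
    fit: PurityPloidyFit,
    states: Optional[Sequence[AllelicState]] = None,
    tau_opt: Optional[float] = None,
) -> tuple[list[Segment], list[Segment]]:
    """Assign each segment its maximum-likelihood allelic state.

    Returns ``(calls, report)``: ``calls`` excludes normal (1,1) segments and
    segments deviating significantly (p < 0.05) from every integral state;
    ``report`` further restricts the calls to segments larger than 2.5 Mb.
    """
    state_set = tuple(states) if states is not None else DEFAULT_STATES
    alpha = fit.alpha
    tau = tau_opt if tau_opt is not None else fit.ploidy

    est = PurityPloidyEstimator(states=state_set)
    arrays = est._prepare(list(segments))
    _, best_idx = est._segment_ll(arrays, alpha, tau)

    calls: list[Segment] = []
    for seg, idx in zip(arrays.segments, best_idx):
        state = state_set[int(idx)]
        seg.state = state
        seg.deviation_p = max(
            _deviation_p(seg, s, alpha, tau) for s in state_set
        )
        if (state.A, state.B, state.clonal_fraction) == (1, 1, 1.0):
            continue
        if seg.deviation_p < DEVIATION_P:
            continue
        calls.append(seg)
    report = [s for s in calls if s.length > REPORT_MIN_BP]
    return calls, report
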