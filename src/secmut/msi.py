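"""Microsatellite-instability scoring from repeat-length read-count tables.

Per locus, the number of distinct repeat lengths with read support exceeding
5% of the best-supported length is counted (loci under 30 reads are excluded).
A locus is unstable when that count n_i strictly exceeds mu_i + 3*sigma_i,
its background mean plus three standard deviations.  The sample-level score is
the percentage of evaluable loci that are unstable; when a matched normal is
available its percentage is subtracted, and a (relative) percentage of 15% or
higher flags the sample as MSI-high.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .records import MicrosatelliteLocus, MsiCall, RepeatLengthDistribution

MIN_LOCUS_DEPTH = 30
SUPPORT_FRACTION = 0.05
MSI_HIGH_THRESHOLD = 15.0
DEFAULT_MIN_EVALUABLE = 1


def polymorphism_count(dist: RepeatLengthDistribution) -> Optional[int]:
    """Distinct repeat lengths with support > 5% of the maximum; None if excluded.

    A locus is excluded (returns ``None``) when its total depth is below 30
    reads or its distribution is empty.
    """
    if not dist.counts or dist.total_depth < MIN_LOCUS_DEPTH:
        return None
    threshold = SUPPORT_FRACTION * max(dist.counts.values())
    return sum(1 for c in dist.counts.values() if c > threshold)


def is_unstable(n_i: int, locus: MicrosatelliteLocus) -> bool:
    """True iff n_i > mu_i + 3*sigma_i (strict inequality)."""
    return n_i > locus.background_mean + 3.0 * locus.background_sd


class MsiScorer:
    """Sample-level MSI caller.

    Parameters
    ----------
    threshold : float
        Relative percentage of unstable loci at or above which the sample is
        MSI-high (default 15).
    min_evaluable : int
        Minimum number of evaluable loci required to produce a call.
    """

    def __init__(
        self,
        threshold: float = MSI_HIGH_THRESHOLD,
        min_evaluable: int = DEFAULT_MIN_EVALUABLE,
    ):
        self.threshold = threshold
        self.min_evaluable = min_evaluable

    def score(
        self,
        tumor_dists: Mapping[str, RepeatLengthDistribution],
        loci: Sequence[MicrosatelliteLocus],
        normal_dists: Optional[Mapping[str, RepeatLengthDistribution]] = None,
    ) -> MsiCall:
        """Score one tumor (and optional matched normal) over a locus panel.

        Each sample's percentage uses its own denominator of evaluable loci;
        loci evaluable in the tumor but not the normal still count toward the
        tumor percentage.
        """
        by_id = {l.locus_id: l for l in loci}

        def _tally(dists: Mapping[str, RepeatLengthDistribution]) -> tuple[int, int]:
            evaluated = unstable = 0
            for locus_id, dist in dists.items():
                locus = by_id.get(locus_id)
                if locus is None:
                    continue
                n_i = polymorphism_count(dist)
                if n_i is None:
                    continue
                evaluated += 1
                if is_unstable(n_i, locus):
                    unstable += 1
            return evaluated, unstable

        n_eval, n_unstable = _tally(tumor_dists)
        if n_eval < self.min_evaluable:
            raise ValueError(
                f"only {n_eval} evaluable loci (minimum {self.min_evaluable})"
            )
        pct_tumor = 100.0 * n_unstable / n_eval

        call = MsiCall(
            n_evaluated=n_eval,
            n_unstable_tumor=n_unstable,
            percent_unstable_tumor=pct_tumor,
        )
        if normal_dists is not None:
            n_eval_n, n_unstable_n = _tally(normal_dists)
            if n_eval_n < self.min_evaluable:
                raise ValueError("no evaluable loci in the matched normal")
            pct_normal = 100.0 * n_unstable_n / n_eval_n
            call.n_evaluated_normal = n_eval_n
            call.n_unstable_normal = n_unstable_n
            call.percent_unstable_normal = pct_normal
            call.relative_percent = pct_tumor - pct_normal
        else:
            call.relative_percent = pct_tumor
        call.msi_high = call.relative_percent >= self.threshold
        return call


def msi_score(
    tumor_dists: Mapping[str, RepeatLengthDistribution],
    loci: Sequence[MicrosatelliteLocus],
    normal_dists: Optional[Mapping[str, RepeatLengthDistribution]] = None,
    threshold: float = MSI_HIGH_THRESHOLD,
) -> MsiCall:
    """Functional wrapper over :class:`MsiScorer`."""
    return MsiScorer(threshold=threshold).score(tumor_dists, loci, normal_dists)
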