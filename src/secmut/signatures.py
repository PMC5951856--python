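"""96-channel mutation spectra and fixed-basis signature exposure fitting.

A tumor's somatic SNVs are tallied into the 96 pyrimidine-centered
trinucleotide channels (:mod:`secmut.channels`).  Exposures to a fixed catalog
of mutational signatures are then obtained by non-negative least squares:
with the signature basis known, per-sample non-negative matrix factorization
reduces to solving

    min_x || c - P^T x ||_2   s.t.  x >= 0

where ``c`` is the 96-vector of counts and ``P`` the signatures-by-channels
probability matrix.  Fractions are the normalized exposures; a signature is
"active" when it accounts for at least 100 mutations or more than 25% of the
total.  UV hallmarks (adjacent CC>TT dinucleotide changes) and the mutation
prevalence per megabase of captured sequence are computed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .channels import CHANNELS, N_CHANNELS, channel_index
from .records import MutationRecord

ACTIVE_MIN_COUNT = 100.0
ACTIVE_MIN_FRACTION = 0.25


@dataclass
class SignatureCatalog:
    """Fixed signature basis: one row per signature over the 96 channels."""

    matrix: np.ndarray  # (n_signatures, 96)
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_CHANNELS:
            raise ValueError("catalog must be (n_signatures, 96)")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("one id per signature row required")
        if np.any(self.matrix < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature row must sum to 1")

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.T, index=list(CHANNELS), columns=list(self.ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureCatalog":
        df = df.reindex(list(CHANNELS))
        if df.isna().any().any():
            raise ValueError("catalog table must cover all 96 channels")
        return cls(df.to_numpy().T, tuple(str(c) for c in df.columns))


@dataclass
class TrinucleotideSpectrum:
    """96-channel SNV count vector for one sample."""

    counts: np.ndarray
    n_errors: int = 0  # records whose context disagreed with their ref allele

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError("spectrum must have 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name="count")


@dataclass
class ExposureProfile:
    """Fitted per-signature exposure fractions for one sample."""

    ids: tuple[str, ...]
    fractions: np.ndarray
    attributed_counts: np.ndarray
    residual_norm: float
    active: set[str] = field(default_factory=set)

    def fraction_of(self, *ids: str) -> float:
        lookup = dict(zip(self.ids, self.fractions))
        return float(sum(lookup.get(i, 0.0) for i in ids))


def build_spectrum(mutations: Iterable[MutationRecord]) -> TrinucleotideSpectrum:
    """Tally SNVs into the 96 channels using their embedded contexts.

    Indels are ignored; purine-reference SNVs are strand-collapsed.  Records
    whose stored context middle base contradicts the ref allele are skipped and
    counted in ``n_errors``.
    """
    counts = np.zeros(N_CHANNELS)
    errors = 0
    for rec in mutations:
        if not rec.is_snv:
            continue
        if rec.context is None:
            errors += 1
            continue
        try:
            counts[channel_index(rec.ref, rec.alt, rec.context)] += 1
        except (ValueError, KeyError):
            errors += 1
    return TrinucleotideSpectrum(counts, n_errors=errors)


class SignatureDecomposer(BaseEstimator, TransformerMixin):
    """Fixed-basis signature exposure estimator (scikit-learn style).

    Parameters
    ----------
    catalog : SignatureCatalog
        The known signature basis; it is not re-estimated, so ``fit`` only
        validates input shape and ``transform`` solves one NNLS problem per
        sample row.
    """

    def __init__(self, catalog: Optional[SignatureCatalog] = None):
        self.catalog = catalog

    def fit(self, X, y=None):
        if self.catalog is None:
            raise ValueError("a SignatureCatalog is required")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_CHANNELS:
            raise ValueError("X must have 96 channels per sample")
        self.catalog_ = self.catalog
        self.n_features_in_ = N_CHANNELS
        return self

    def transform(self, X) -> np.ndarray:
        """Exposure fractions, one row per input spectrum."""
        check_is_fitted(self, "catalog_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.catalog_.n_signatures))
        for i, row in enumerate(X):
            out[i] = self._profile(row).fractions
        return out

    def _profile(self, counts: np.ndarray) -> ExposureProfile:
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot decompose an empty spectrum")
        exposures, rnorm = nnls(self.catalog_.matrix.T, counts)
        s = exposures.sum()
        fractions = exposures / s if s > 0 else exposures
        attributed = fractions * total
        profile = ExposureProfile(
            ids=self.catalog_.ids,
            fractions=fractions,
            attributed_counts=attributed,
            residual_norm=float(rnorm),
        )
        profile.active = active_signatures(profile, int(round(total)))
        return profile


def fit_exposures(
    spectrum: TrinucleotideSpectrum, catalog: SignatureCatalog
) -> ExposureProfile:
    """NNLS exposure fit of one spectrum against a fixed catalog."""
    dec = SignatureDecomposer(catalog).fit(spectrum.counts[None, :])
    return dec._profile(spectrum.counts)


def active_signatures(profile: ExposureProfile, total_mutations: int) -> set[str]:
    """Signatures contributing >=100 mutations or >25% of the total."""
    if total_mutations < 0:
        raise ValueError("total_mutations must be non-negative")
    return {
        sid
        for sid, frac, count in zip(
            profile.ids, profile.fractions, profile.attributed_counts
        )
        if count >= ACTIVE_MIN_COUNT or frac > ACTIVE_MIN_FRACTION
    }


def count_cc_tt(mutations: Sequence[MutationRecord]) -> int:
    """Count adjacent CC>TT (or GG>AA on the other strand) dinucleotide changes.

    Input must be sorted by (chrom, pos); each qualifying adjacent pair is
    counted once.
    """
    snvs = [m for m in mutations if m.is_snv]
    n = 0
    for a, b in zip(snvs, snvs[1:]):
        if a.chrom != b.chrom or b.pos != a.pos + 1:
            continue
        if a.ref == "C" and a.alt == "T" and b.ref == "C" and b.alt == "T":
            n += 1
        elif a.ref == "G" and a.alt == "A" and b.ref == "G" and b.alt == "A":
            # GG>AA is CC>TT read from the opposite strand
            n += 1
    return n


def mutation_prevalence(n_mutations: int, capture_size_mb: float) -> float:
    """Somatic mutations per megabase of captured sequence."""
    if capture_size_mb <= 0:
        raise ValueError("capture size must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    return n_mutations / capture_size_mb


def format_prevalence(value: float) -> float:
    """Round a prevalence to 3 significant figures for reporting."""
    if value == 0:
        return 0.0
    from math import floor, log10

    digits = 2 - floor(log10(abs(value)))
    return round(value, digits)
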