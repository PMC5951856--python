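"""Three-class tumor assignment: MSI, UV-damage, or pauci-mutational.

A tumor profile combines mutation prevalence (per Mb), signature exposure
fractions, the indel fraction and an optional MSI call.  Rules, in precedence
order:

* MSI   -- mismatch-repair signatures (6 + 15) exceed 30% of mutations, OR the
           catalog is at least 30% indels, OR the sample is MSI-high.
* UV    -- UV signatures (7 + 11) exceed 30% on a high-burden tumor
           (prevalence >= 10/Mb).
* PAUCI -- prevalence below the pauci ceiling (default 10/Mb, chosen inside
           the empty gap between low- and high-burden tumors).

MSI outranks UV when both fire (a mixed-signature flag is raised); a profile
satisfying no rule is assigned its nearest rule with a low-confidence flag,
never left unclassified.  The module also screens the mismatch-repair genes
MLH1/MSH2/MSH6/PMS2 for disruptive alterations (nonsense SNVs, frameshift
indels, somatic gene losses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import MsiCall, MutationRecord
from .signatures import ExposureProfile

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

DISRUPTIVE_CONSEQUENCES = {
    "nonsense",
    "stop_gained",
    "frameshift",
    "frameshift_insertion",
    "frameshift_deletion",
}


@dataclass
class ClassThresholds:
    """Tunable decision thresholds of the three-class rule engine."""

    msi_signature_ids: tuple[str, ...] = ("6", "15")
    uv_signature_ids: tuple[str, ...] = ("7", "11")
    msi_exposure_min: float = 0.30     # strict >
    indel_fraction_min: float = 0.30   # inclusive >=
    uv_exposure_min: float = 0.30      # strict >
    high_burden_min: float = 10.0      # per Mb, for the UV rule
    pauci_ceiling: float = 10.0        # per Mb


@dataclass
class TumorProfile:
    """Per-sample evidence consumed by the classifier."""

    sample_id: str
    n_snv: int
    n_indel: int
    prevalence: float  # mutations per Mb
    exposures: Optional[ExposureProfile] = None
    msi: Optional[MsiCall] = None
    cc_tt_count: int = 0
    purity: Optional[float] = None

    @property
    def indel_fraction(self) -> float:
        total = self.n_snv + self.n_indel
        return self.n_indel / total if total else 0.0

    def exposure_of(self, ids: Sequence[str]) -> float:
        if self.exposures is None:
            return 0.0
        return self.exposures.fraction_of(*ids)


@dataclass
class ClassCall:
    """Final class with every rule's evaluated evidence."""

    sample_id: str
    tumor_class: str  # MSI | UV | PAUCI
    evidence: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tumor_class not in {"MSI", "UV", "PAUCI"}:
            raise ValueError(f"unknown class {self.tumor_class!r}")


class TumorClassifier(BaseEstimator):
    """Rule-based three-class tumor classifier (sklearn predict-style).

    The rules are fixed by the thresholds given at construction; ``fit`` is a
    no-op provided for pipeline compatibility, and ``predict`` maps profiles
    to class labels.
    """

    def __init__(self, thresholds: Optional[ClassThresholds] = None):
        self.thresholds = thresholds

    def fit(self, X=None, y=None):
        self.thresholds_ = self.thresholds or ClassThresholds()
        return self

    def classify(self, profile: TumorProfile) -> ClassCall:
        if not hasattr(self, "thresholds_"):
            self.fit()
        th = self.thresholds_
        msi_expo = profile.exposure_of(th.msi_signature_ids)
        uv_expo = profile.exposure_of(th.uv_signature_ids)
        indel_frac = profile.indel_fraction
        msi_high = bool(profile.msi.msi_high) if profile.msi is not None else False

        evidence = {
            "msi_signature_exposure": msi_expo,
            "uv_signature_exposure": uv_expo,
            "indel_fraction": indel_frac,
            "msi_high": float(msi_high),
            "prevalence_per_mb": profile.prevalence,
            "cc_tt_count": float(profile.cc_tt_count),
        }

        msi_fires = (
            msi_expo > th.msi_exposure_min
            or indel_frac >= th.indel_fraction_min
            or msi_high
        )
        uv_fires = (
            uv_expo > th.uv_exposure_min
            and profile.prevalence >= th.high_burden_min
        )

        flags: set[str] = set()
        if msi_fires:
            if uv_fires:
                flags.add("mixed-signature")
            return ClassCall(profile.sample_id, "MSI", evidence, flags)
        if uv_fires:
            return ClassCall(profile.sample_id, "UV", evidence, flags)
        if profile.prevalence < th.pauci_ceiling:
            return ClassCall(profile.sample_id, "PAUCI", evidence, flags)

        # No rule satisfied: nearest rule by normalized distance to its boundary.
        flags.add("low-confidence")
        distances = {
            "MSI": max(th.msi_exposure_min - msi_expo, 0.0) / max(th.msi_exposure_min, 1e-9),
            "UV": max(th.uv_exposure_min - uv_expo, 0.0) / max(th.uv_exposure_min, 1e-9),
            "PAUCI": max(profile.prevalence - th.pauci_ceiling, 0.0)
            / max(th.pauci_ceiling, 1e-9),
        }
        nearest = min(distances, key=lambda k: (distances[k], k))
        return ClassCall(profile.sample_id, nearest, evidence, flags)

    def predict(self, profiles: Iterable[TumorProfile]) -> np.ndarray:
        return np.array([self.classify(p).tumor_class for p in profiles])


def classify_tumor(
    profile: TumorProfile, thresholds: Optional[ClassThresholds] = None
) -> ClassCall:
    """Classify one tumor profile; see :class:`TumorClassifier`."""
    return TumorClassifier(thresholds).fit().classify(profile)


def purity_from_vaf(records: Sequence[MutationRecord]) -> Optional[float]:
    """Crude purity sanity check: twice the median somatic variant allele fraction."""
    vafs = [r.vaf for r in records if r.vaf is not None]
    if not vafs:
        return None
    return min(2.0 * float(np.median(vafs)), 1.0)


@dataclass
class MmrEvent:
    gene: str
    kind: str  # nonsense | frameshift | gene_loss
    origin: str  # somatic | germline
    detail: str = ""


def screen_mmr_genes(
    variants: Sequence[MutationRecord],
    gene_list: Sequence[str] = MMR_GENES,
    cn_losses: Optional[Sequence[Mapping[str, str]]] = None,
) -> list[MmrEvent]:
    """Disruptive mismatch-repair alterations on the configured gene list.

    Reported: somatic and germline nonsense SNVs, somatic and germline
    frameshifting indels, and somatic gene losses (from ``cn_losses``, items
    with ``gene`` and optional ``detail`` keys).  Variants without an annotated
    consequence are skipped with a warning.
    """
    genes = set(gene_list)
    events: list[MmrEvent] = []
    for v in variants:
        if v.gene not in genes:
            continue
        if v.consequence is None:
            warnings.warn(
                f"variant {v.chrom}:{v.pos} in {v.gene} lacks a consequence "
                "annotation; skipped",
                stacklevel=2,
            )
            continue
        cons = v.consequence.lower()
        if cons not in DISRUPTIVE_CONSEQUENCES:
            continue
        kind = "nonsense" if cons in {"nonsense", "stop_gained"} else "frameshift"
        events.append(
            MmrEvent(v.gene, kind, v.origin or "somatic", f"{v.chrom}:{v.pos}")
        )
    for loss in cn_losses or []:
        if loss["gene"] in genes:
            events.append(
                MmrEvent(loss["gene"], "gene_loss", "somatic", str(loss.get("detail", "")))
            )
    return events


def calls_to_frame(calls: Sequence[ClassCall]) -> pd.DataFrame:
    """Machine-readable classification report."""
    rows = []
    for c in calls:
        row = {"sample": c.sample_id, "class": c.tumor_class, **c.evidence}
        row["flags"] = ";".join(sorted(c.flags))
        rows.append(row)
    return pd.DataFrame(rows)
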