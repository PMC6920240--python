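"""Identify which signature genes are transcription factors and split the
profile by injury/repair involvement."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_io import (
    ConfigurationError,
    Direction,
    GeneId,
    GeneSetCollection,
    SignatureTable,
    ValidationError,
)

logger = logging.getLogger("tfsigkit")


@dataclass(frozen=True)
class TfRecord:
    tf: GeneId
    direction: Direction
    injury: bool
    source_sets: tuple[str, ...]


@dataclass
class TfProfile:
    records: list[TfRecord]

    def __post_init__(self):
        syms = [r.tf.symbol for r in self.records]
        if len(syms) != len(set(syms)):
            raise ValidationError("duplicate TFs in profile")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def symbols(self) -> set[str]:
        return {r.tf.symbol for r in self.records}


def identify_tfs(signature: SignatureTable, tf_catalog: GeneSetCollection) -> TfProfile:
    """Signature genes present in any catalog set (union semantics).

    Direction and injury flags are carried through from the signature;
    ``source_sets`` lists every catalog set containing the gene.
    """
    if len(tf_catalog) == 0:
        raise ConfigurationError("TF catalog is empty")
    membership: dict[str, list[str]] = {}
    for s in tf_catalog.sets:
        for sym in s.member_symbols:
            membership.setdefault(sym, []).append(s.set_id)
    records = [
        TfRecord(
            tf=rec.gene,
            direction=rec.direction,
            injury=rec.injury,
            source_sets=tuple(sorted(membership[rec.gene.symbol])),
        )
        for rec in signature.records
        if rec.gene.symbol in membership
    ]
    profile = TfProfile(records)
    logger.info(
        "identify_tfs: %d of %d signature genes found in a %d-set catalog",
        len(profile), len(signature), len(tf_catalog),
    )
    return profile


def partition_by_injury(profile: TfProfile) -> tuple[TfProfile, TfProfile]:
    """Split into (injury/repair TFs, remaining TFs) on the injury flag."""
    if len(profile) == 0:
        raise ValidationError("cannot partition an empty TF profile")
    injury = [r for r in profile.records if r.injury]
    other = [r for r in profile.records if not r.injury]
    logger.info("partition_by_injury: %d injury, %d other", len(injury), len(other))
    return TfProfile(injury), TfProfile(other)


@dataclass(frozen=True)
class ProfileSummary:
    n_total: int
    n_injury: int
    pct_injury: int  # rounded to nearest integer percent
    n_up: int
    n_down: int


def summarize_profile(profile: TfProfile) -> ProfileSummary:
    """Headline counts: total TFs, injury-involved TFs, and the rounded
    injury percentage (e.g. 32 of 92 -> 35%)."""
    if len(profile) == 0:
        raise ValidationError("cannot summarize an empty TF profile")
    n_total = len(profile)
    n_injury = sum(1 for r in profile.records if r.injury)
    return ProfileSummary(
        n_total=n_total,
        n_injury=n_injury,
        pct_injury=int(round(100.0 * n_injury / n_total)),
        n_up=sum(1 for r in profile.records if r.direction is Direction.UP),
        n_down=sum(1 for r in profile.records if r.direction is Direction.DOWN),
    )
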