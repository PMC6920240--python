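"""Multi-study ChIP-seq peak processing: cross-study reproducible-peak
clustering, intensity/support filtering, TSS-window peak-to-gene
assignment, signature-restricted intensity ranking, and proposal of
binding-site / negative-control qPCR regions.

All coordinates are 0-based half-open. Two peaks belong to the same
cluster when their intervals share at least one base (single linkage
across all studies); a gene is assigned to a cluster when its TSS lies
within ``window`` bp of the cluster envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core_io import (
    ConfigurationError,
    GeneAnnotationTable,
    GeneId,
    Peak,
    PeakSet,
    SignatureTable,
    ValidationError,
)

logger = logging.getLogger("tfsigkit")


@dataclass
class PeakCluster:
    """Envelope of overlapping peaks across studies."""

    chrom: str
    start: int
    end: int
    members: list[Peak]
    studies: frozenset[str]
    intensity: float  # max over member peaks

    def __post_init__(self):
        if not self.members:
            raise ValidationError("cluster with no member peaks")
        for p in self.members:
            if p.chrom != self.chrom or p.end <= self.start or p.start >= self.end:
                raise ValidationError("member peak outside cluster envelope")
        if self.studies != frozenset(p.study_id for p in self.members):
            raise ValidationError("cluster study set inconsistent with members")


def harmonize_studies(peaksets: list[PeakSet]) -> list[PeakCluster]:
    """Single-linkage merge of peaks overlapping by >= 1 bp, per chromosome,
    pooled over all studies. Clusters are sorted by (chrom, start)."""
    study_ids = [ps.study_id for ps in peaksets]
    if len(study_ids) != len(set(study_ids)):
        dup = sorted({s for s in study_ids if study_ids.count(s) > 1})
        raise ValidationError(f"duplicate study ids across peak sets: {dup}")
    pooled = sorted(
        (p for ps in peaksets for p in ps.peaks),
        key=lambda p: (p.chrom, p.start, p.end, p.study_id),
    )
    clusters: list[PeakCluster] = []
    current: list[Peak] = []
    cur_chrom, cur_end = None, None

    def _flush():
        if current:
            clusters.append(
                PeakCluster(
                    chrom=cur_chrom,
                    start=min(p.start for p in current),
                    end=max(p.end for p in current),
                    members=list(current),
                    studies=frozenset(p.study_id for p in current),
                    intensity=max(p.intensity for p in current),
                )
            )

    for p in pooled:
        if current and p.chrom == cur_chrom and p.start < cur_end:
            current.append(p)
            cur_end = max(cur_end, p.end)
        else:
            _flush()
            current = [p]
            cur_chrom, cur_end = p.chrom, p.end
    _flush()
    logger.info(
        "harmonize_studies: %d peaks from %d studies -> %d clusters",
        len(pooled), len(peaksets), len(clusters),
    )
    return clusters


def filter_peaks(
    clusters: list[PeakCluster],
    min_intensity: float = 10.0,
    min_studies: int = 2,
) -> list[PeakCluster]:
    """Keep clusters with intensity >= min_intensity (inclusive) seen in at
    least min_studies distinct studies."""
    kept = [
        c for c in clusters
        if c.intensity >= min_intensity and len(c.studies) >= min_studies
    ]
    logger.info(
        "filter_peaks: %d of %d clusters pass intensity >= %g and studies >= %d",
        len(kept), len(clusters), min_intensity, min_studies,
    )
    return kept


@dataclass(frozen=True)
class PeakAssignment:
    cluster: PeakCluster
    gene: GeneId
    distance: int  # bp from TSS to the nearest envelope edge; 0 if inside
    in_signature: bool

    def __post_init__(self):
        if self.distance < 0:
            raise ValidationError("negative assignment distance")


def assign_genes(
    clusters: list[PeakCluster],
    annotation: GeneAnnotationTable,
    window: int = 10_000,
) -> list[PeakAssignment]:
    """Assign a gene to a cluster when its TSS lies in
    [cluster.start - window, cluster.end + window) (half-open).

    Distance is 0 for a TSS inside the envelope, else the bp gap to the
    nearest edge. One row per (cluster, gene) pair, in (chrom, start,
    symbol) order.
    """
    if window < 0:
        raise ConfigurationError(f"window must be >= 0, got {window}")
    assignments: list[PeakAssignment] = []
    by_chrom: dict[str, list] = {}
    for rec in annotation:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for c in clusters:
        for rec in by_chrom.get(c.chrom, ()):
            tss = rec.tss
            if not (c.start - window <= tss < c.end + window):
                continue
            if c.start <= tss < c.end:
                dist = 0
            elif tss < c.start:
                dist = c.start - tss
            else:
                # half-open envelope: end is the first position past the peak
                dist = tss - c.end
            assignments.append(
                PeakAssignment(cluster=c, gene=rec.gene, distance=dist, in_signature=False)
            )
    assignments.sort(key=lambda a: (a.cluster.chrom, a.cluster.start, a.gene.symbol))
    logger.info("assign_genes: %d assignments within %d bp", len(assignments), window)
    return assignments


def prioritize(
    assignments: list[PeakAssignment],
    signature: SignatureTable,
) -> pd.DataFrame:
    """Signature-restricted, intensity-ranked target table.

    Assignments whose gene is not in the signature are dropped; survivors
    are sorted by cluster intensity descending, then study support
    descending, then gene symbol ascending (stable).
    """
    sig_syms = signature.symbols()
    rows = []
    for a in assignments:
        in_sig = a.gene.symbol in sig_syms
        if not in_sig:
            continue
        rows.append(
            {
                "gene": a.gene.symbol,
                "chrom": a.cluster.chrom,
                "peak_start": a.cluster.start,
                "peak_end": a.cluster.end,
                "intensity": a.cluster.intensity,
                "n_studies": len(a.cluster.studies),
                "distance": a.distance,
                "direction": signature[a.gene.symbol].direction.value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "peak_start", "peak_end", "intensity",
                 "n_studies", "distance", "direction"],
    )
    if len(df):
        df = df.sort_values(
            ["intensity", "n_studies", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    logger.info(
        "prioritize: %d of %d assignments map to signature genes",
        len(df), len(assignments),
    )
    return df


@dataclass(frozen=True)
class PrimerRegion:
    gene: GeneId
    kind: str  # "binding_site" | "negative_control"
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.kind not in ("binding_site", "negative_control"):
            raise ValidationError(f"unknown region kind {self.kind!r}")
        if self.start >= self.end:
            raise ValidationError("empty primer region")


def propose_regions(
    gene: GeneId,
    cluster: PeakCluster,
    annotation: GeneAnnotationTable,
    control_offset: int = 5_000,
) -> tuple[PrimerRegion, PrimerRegion]:
    """Binding-site region (the cluster envelope) plus a same-length
    negative-control region centered ``control_offset`` bp 5' of the TSS,
    shifted further 5' until disjoint from the binding site and clipped
    at coordinate 0."""
    if gene.symbol not in annotation:
        raise LookupError(f"gene {gene.symbol} absent from annotation")
    rec = annotation[gene.symbol]
    binding = PrimerRegion(gene, "binding_site", cluster.chrom, cluster.start, cluster.end)
    length = cluster.end - cluster.start
    sign = -1 if rec.strand == "+" else +1  # 5' direction along the chromosome
    center = rec.tss + sign * control_offset

    def _interval(center_pos: int) -> tuple[int, int]:
        start = center_pos - length // 2
        return start, start + length

    start, end = _interval(center)
    # march 5' in region-length steps until clear of the binding site
    while start < binding.end and end > binding.start:
        center += sign * length
        start, end = _interval(center)
    if start < 0:
        end -= start
        start = 0
        if end > binding.start and start < binding.end:
            # clipping pushed us back onto the binding site: place 3' instead
            start = binding.end + control_offset
            end = start + length
    return binding, PrimerRegion(gene, "negative_control", rec.chrom, start, end)
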