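"""Seeded generators for every pipeline input, with planted ground truth.

Each generator is a pure function of (seed, parameters): the same call
produces bit-identical data, and the returned :class:`GroundTruth` records
what was planted so downstream recovery can be asserted exactly.

Defaults mirror the study conditions the pipeline was designed around:
a universe of 10,271 genes, a signature of 775 up- plus 740 down-regulated
genes of which ~6% are transcription factors and ~35% of those carry an
injury/repair annotation; 13 assayed TFs against 3 housekeeping genes with
Gaussian Ct noise of 0.3 cycles; ChIP enrichment of 8-fold over the IgG
background at 20% CV.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ConfigurationError,
    CtMatrix,
    Direction,
    GeneAnnotation,
    GeneAnnotationTable,
    GeneId,
    GeneSet,
    GeneSetCollection,
    Peak,
    PeakSet,
    SignatureRecord,
    SignatureTable,
)

# study-scale defaults
N_UNIVERSE = 10_271
N_UP = 775
N_DOWN = 740
TF_FRACTION = 0.06
INJURY_FRACTION = 0.35
NOISE_SD = 0.3          # cycles, Gaussian on the Ct scale
CHIP_FOLD = 8.0
CHIP_CV = 0.2
N_ASSAY_TFS = 13
N_HOUSEKEEPING = 3
TIMEPOINTS = ("1wk", "2wk", "5wk", "10wk", "KF")


@dataclass
class GroundTruth:
    """What the generators planted, serialized alongside every dataset."""

    seed: int
    planted_tfs: list[str] = field(default_factory=list)
    planted_injury_tfs: list[str] = field(default_factory=list)
    planted_enriched_sets: dict[str, float] = field(default_factory=dict)
    planted_reproducible_peaks: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)
    planted_ct_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = NOISE_SD
    chip_fold: float = CHIP_FOLD

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_reproducible_peaks"] = [
            (g, tuple(iv), inten) for g, iv, inten in raw.get("planted_reproducible_peaks", [])
        ]
        return cls(**raw)


def _gene_symbols(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


@dataclass
class SignatureWorld:
    universe: list[GeneId]
    signature: SignatureTable
    tf_catalog: GeneSetCollection
    truth: GroundTruth


def generate_signature_world(
    seed: int,
    n_universe: int = N_UNIVERSE,
    n_up: int = N_UP,
    n_down: int = N_DOWN,
    tf_fraction: float = TF_FRACTION,
    injury_fraction: float = INJURY_FRACTION,
) -> SignatureWorld:
    """Universe, directional signature, and a TF catalog whose only
    signature members are the planted TFs."""
    if n_up + n_down > n_universe:
        raise ConfigurationError("signature larger than universe")
    if not (0.0 <= tf_fraction <= 1.0 and 0.0 <= injury_fraction <= 1.0):
        raise ConfigurationError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    symbols = _gene_symbols(n_universe)
    universe = [GeneId(s) for s in symbols]

    sig_idx = rng.choice(n_universe, size=n_up + n_down, replace=False)
    sig_syms = [symbols[i] for i in sig_idx]
    up_syms, down_syms = sig_syms[:n_up], sig_syms[n_up:]

    n_tfs = int(round(tf_fraction * len(sig_syms)))
    tf_pick = rng.choice(len(sig_syms), size=n_tfs, replace=False)
    planted_tfs = sorted(sig_syms[i] for i in tf_pick)
    n_injury_tfs = int(round(injury_fraction * n_tfs))
    injury_tfs = set(
        np.array(planted_tfs)[rng.choice(n_tfs, size=n_injury_tfs, replace=False)]
    ) if n_tfs else set()

    planted = set(planted_tfs)
    records = []
    for sym in sig_syms:
        if sym in planted:
            injury = sym in injury_tfs
        else:
            injury = bool(rng.random() < injury_fraction)
        records.append(
            SignatureRecord(
                gene=GeneId(sym),
                direction=Direction.UP if sym in set(up_syms) else Direction.DOWN,
                injury=injury,
            )
        )
    signature = SignatureTable(records)

    # catalog decoys: TFs that are not in the signature, so identify_tfs
    # must return exactly the planted set
    non_sig = sorted(set(symbols) - set(sig_syms))
    n_decoys = max(len(planted_tfs), 4)
    decoys = [non_sig[i] for i in rng.choice(len(non_sig), size=n_decoys, replace=False)]
    pool = planted_tfs + decoys
    half = len(pool) // 2
    catalog = GeneSetCollection(
        [
            GeneSet("TF_CATALOG_A", "synthetic TF catalog, part A",
                    tuple(GeneId(s) for s in sorted(pool[:half]))),
            GeneSet("TF_CATALOG_B", "synthetic TF catalog, part B",
                    tuple(GeneId(s) for s in sorted(pool[half:]))),
        ]
    )
    truth = GroundTruth(
        seed=seed,
        planted_tfs=planted_tfs,
        planted_injury_tfs=sorted(injury_tfs),
    )
    return SignatureWorld(universe, signature, catalog, truth)


def generate_target_db(
    seed: int,
    world: SignatureWorld,
    n_enriched_sets: int = 3,
    n_null_sets: int = 20,
    overlap_rate: float = 0.6,
    set_size_range: tuple[int, int] = (50, 200),
) -> GeneSetCollection:
    """TF-target database with planted enriched sets.

    Enriched sets draw ``overlap_rate`` of their members from the
    up-signature and the rest from the remaining universe; null sets are
    uniform draws. Enriched sets are named after planted signature TFs
    when available so the signature-overlap stage has a non-empty answer.
    Updates ``world.truth.planted_enriched_sets`` in place.
    """
    lo, hi = set_size_range
    if hi > len(world.universe):
        raise ConfigurationError("set size exceeds universe")
    rng = np.random.default_rng(seed)
    symbols = [g.symbol for g in world.universe]
    up = sorted(world.signature.symbols(Direction.UP))
    non_up = sorted(set(symbols) - set(up))

    sets: list[GeneSet] = []
    for i in range(n_enriched_sets):
        size = int(rng.integers(lo, hi + 1))
        k = int(round(overlap_rate * size))
        members = [up[j] for j in rng.choice(len(up), size=min(k, len(up)), replace=False)]
        members += [non_up[j] for j in rng.choice(len(non_up), size=size - len(members), replace=False)]
        tf = world.truth.planted_tfs[i] if i < len(world.truth.planted_tfs) else f"ETF{i + 1}"
        set_id = f"{tf}_exp{i + 1}"
        sets.append(GeneSet(set_id, "planted enriched target set",
                            tuple(GeneId(s) for s in members)))
        world.truth.planted_enriched_sets[set_id] = overlap_rate
    for i in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = [symbols[j] for j in rng.choice(len(symbols), size=size, replace=False)]
        sets.append(GeneSet(f"NULLTF{i + 1}_exp1", "null target set",
                            tuple(GeneId(s) for s in members)))
    return GeneSetCollection(sets)


@dataclass
class PeakWorld:
    annotation: GeneAnnotationTable
    peaksets: list[PeakSet]
    truth: GroundTruth


def generate_peak_studies(
    seed: int,
    annotation_size: int = 200,
    n_studies: int = 3,
    n_true_sites: int = 20,
    n_noise_peaks_per_study: int = 50,
    true_intensity: tuple[float, float] = (10.0, 100.0),
    noise_intensity: tuple[float, float] = (1.0, 9.5),
    gene_spacing: int = 50_000,
    site_halfwidth: int = 300,
    jitter: int = 100,
) -> PeakWorld:
    """Synthetic genome with multi-study peak sets.

    True binding sites sit within 10 kb of a planted gene's TSS, recur in
    >= 2 studies with jittered boundaries (jitter < halfwidth keeps >= 1 bp
    overlap), and carry intensity >= 10. Noise is either low-intensity
    (below 10, anywhere) or high-intensity but confined to one study near
    study-reserved non-planted genes, so the reproducibility filter removes
    it deterministically.
    """
    if n_studies < 2:
        raise ConfigurationError("need >= 2 studies for reproducibility filtering")
    if n_true_sites > annotation_size:
        raise ConfigurationError("more true sites than genes")
    if annotation_size * gene_spacing > 2**31:
        raise ConfigurationError("genome too large; reduce annotation_size or spacing")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    gene_len = 2_000
    symbols = _gene_symbols(annotation_size, prefix="PG")
    records = []
    for i, sym in enumerate(symbols):
        start = 20_000 + i * gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(GeneAnnotation(GeneId(sym), chrom, strand, start, start + gene_len))
    annotation = GeneAnnotationTable(records)

    planted_idx = sorted(rng.choice(annotation_size, size=n_true_sites, replace=False))
    planted = [records[i] for i in planted_idx]
    planted_syms = {r.gene.symbol for r in planted}

    study_peaks: dict[str, list[Peak]] = {f"s{j + 1}": [] for j in range(n_studies)}
    truth_sites = []
    for rec in planted:
        center = rec.tss + int(rng.integers(-2_000, 2_001))
        n_emit = int(rng.integers(2, n_studies + 1))
        emit_in = rng.choice(n_studies, size=n_emit, replace=False)
        best = 0.0
        env_start, env_end = math.inf, -math.inf
        for j in emit_in:
            s = center - site_halfwidth + int(rng.integers(-jitter, jitter + 1))
            e = center + site_halfwidth + int(rng.integers(-jitter, jitter + 1))
            inten = float(rng.uniform(*true_intensity))
            best = max(best, inten)
            env_start, env_end = min(env_start, s), max(env_end, e)
            study_peaks[f"s{j + 1}"].append(Peak(chrom, max(s, 0), e, inten, f"s{j + 1}"))
        truth_sites.append((rec.gene.symbol, (int(env_start), int(env_end)), best))

    non_planted = [r for r in records if r.gene.symbol not in planted_syms]
    # low-intensity noise lives in intergenic midzones, clear of every TSS
    # window and of the study-reserved high-noise bands, so no mixed
    # low+high cluster can ever span two studies
    mid_jitter = max(gene_spacing // 2 - 13_000, 0)
    for j in range(n_studies):
        sid = f"s{j + 1}"
        n_low = n_noise_peaks_per_study // 2
        for _ in range(n_low):
            i = int(rng.integers(1, annotation_size))
            pos = 20_000 + i * gene_spacing - gene_spacing // 2
            pos += int(rng.integers(-mid_jitter, mid_jitter + 1))
            length = int(rng.integers(200, 801))
            study_peaks[sid].append(
                Peak(chrom, pos, pos + length, float(rng.uniform(*noise_intensity)), sid)
            )
        # high-intensity single-study noise near study-reserved genes
        reserved = [r for idx, r in enumerate(non_planted) if idx % n_studies == j]
        for _ in range(n_noise_peaks_per_study - n_low):
            if not reserved:
                break
            rec = reserved[int(rng.integers(0, len(reserved)))]
            pos = rec.tss + int(rng.integers(-5_000, 5_001))
            length = int(rng.integers(200, 801))
            study_peaks[sid].append(
                Peak(chrom, max(pos, 0), max(pos, 0) + length,
                     float(rng.uniform(*true_intensity)), sid)
            )
    peaksets = [
        PeakSet(sorted(study_peaks[f"s{j + 1}"], key=lambda p: (p.chrom, p.start, p.end)),
                f"s{j + 1}")
        for j in range(n_studies)
    ]
    truth = GroundTruth(seed=seed, planted_reproducible_peaks=truth_sites)
    return PeakWorld(annotation, peaksets, truth)


def signature_for_peak_world(
    seed: int,
    world: PeakWorld,
    extra_fraction: float = 0.25,
) -> SignatureTable:
    """Signature containing every planted peak gene plus a random fraction
    of the remaining annotated genes (decoys untouched by true peaks)."""
    rng = np.random.default_rng(seed)
    planted = {g for g, _, _ in world.truth.planted_reproducible_peaks}
    records = []
    for rec in world.annotation:
        sym = rec.gene.symbol
        if sym in planted or rng.random() < extra_fraction:
            records.append(
                SignatureRecord(
                    gene=rec.gene,
                    direction=Direction.UP if rng.random() < 0.5 else Direction.DOWN,
                    injury=bool(rng.random() < INJURY_FRACTION),
                )
            )
    return SignatureTable(records)


def generate_ct_dataset(
    seed: int,
    n_assays: int = N_ASSAY_TFS,
    n_housekeeping: int = N_HOUSEKEEPING,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    replicates: int = 6,
    effects: dict[str, dict[str, float]] | None = None,
    noise_sd: float = NOISE_SD,
    plate_offset_sd: float = 0.5,
) -> tuple[CtMatrix, GroundTruth]:
    """Factorial (genotype x treatment x timepoint) Ct matrix.

    ``effects`` maps target assay -> {"genotype": d, "treatment": d,
    "interaction": d} in delta-Ct units, applied to KO, DCVC, and
    KO&DCVC samples respectively; housekeeping assays receive only the
    per-sample plate offset and noise, so delta-Ct normalization recovers
    the planted shifts.
    """
    if replicates < 2:
        raise ConfigurationError("need >= 2 replicates per cell")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    assays = [f"TF{i:02d}" for i in range(1, n_assays + 1)]
    hk = [f"HK{i}" for i in range(1, n_housekeeping + 1)]
    effects = effects or {}
    baselines = {a: float(rng.uniform(20.0, 28.0)) for a in assays + hk}

    rows, meta_rows = [], []
    for tp in timepoints:
        for geno in ("WT", "KO"):
            for treat in ("PBS", "DCVC"):
                for r in range(1, replicates + 1):
                    sample = f"{tp}_{geno}_{treat}_{r}"
                    offset = float(rng.normal(0.0, plate_offset_sd))
                    vals = {}
                    for a in assays:
                        eff = effects.get(a, {})
                        shift = 0.0
                        if geno == "KO":
                            shift += eff.get("genotype", 0.0)
                        if treat == "DCVC":
                            shift += eff.get("treatment", 0.0)
                        if geno == "KO" and treat == "DCVC":
                            shift += eff.get("interaction", 0.0)
                        vals[a] = baselines[a] + shift + offset + float(rng.normal(0, noise_sd))
                    for a in hk:
                        vals[a] = baselines[a] + offset + float(rng.normal(0, noise_sd))
                    rows.append(pd.Series(vals, name=sample))
                    meta_rows.append(
                        {"sample": sample, "genotype": geno, "treatment": treat,
                         "timepoint": tp}
                    )
    values = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    roles = {a: "target_gene" for a in assays} | {h: "housekeeping" for h in hk}
    truth = GroundTruth(
        seed=seed,
        planted_ct_effects={a: dict(effects.get(a, {})) for a in assays},
        noise_sd=noise_sd,
    )
    return CtMatrix(values=values, metadata=meta, roles=roles), truth


def generate_chip_dataset(
    seed: int,
    n_replicates: int = 3,
    chip_fold: float = CHIP_FOLD,
    cv: float = CHIP_CV,
    baseline_pct: float = 0.1,
    input_fraction: float = 0.01,
    input_ct: float = 25.0,
    region: str = "promoter",
) -> tuple[pd.DataFrame, GroundTruth]:
    """ChIP-qPCR Ct table for an antibody x region design.

    The target antibody at the binding region recovers
    ``chip_fold * baseline_pct`` percent of input; the three control
    cells sit at ``baseline_pct``. Percent-input draws are lognormal at
    the given CV and back-converted to IP Ct values against a common
    dilution-adjusted input.
    """
    if n_replicates < 2:
        raise ConfigurationError("need >= 2 replicates (independent ChIPs)")
    if chip_fold <= 0:
        raise ConfigurationError("chip_fold must be > 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    adjusted_input = input_ct - math.log2(1.0 / input_fraction)
    rows = []
    for antibody in ("target_antibody", "control_IgG"):
        for region_kind in ("binding", "nonbinding"):
            mean_pct = baseline_pct * (
                chip_fold if (antibody == "target_antibody" and region_kind == "binding") else 1.0
            )
            for r in range(1, n_replicates + 1):
                pct = mean_pct * math.exp(float(rng.normal(0.0, sigma)))
                ip_ct = adjusted_input - math.log2(pct / 100.0)
                rows.append(
                    {"antibody": antibody, "region_kind": region_kind,
                     "region": region, "replicate": r,
                     "ip_ct": ip_ct, "input_ct": input_ct}
                )
    df = pd.DataFrame(rows)
    truth = GroundTruth(seed=seed, chip_fold=chip_fold)
    return df, truth
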