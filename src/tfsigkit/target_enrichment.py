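"""Representation-factor enrichment of TF target sets against a directional
gene signature, and hypergeometric overrepresentation analysis (ORA) of
gene lists against pathway categories.

The representation factor (RF) is the observed overlap between a target
set and a signature list divided by the overlap expected if the two sets
were drawn independently from a common universe of N genes:

    RF = x / (n * D / N) = x * N / (n * D)

with x the overlap count, n the target-set size, D the signature-list
size and N the universe size. RF > 1 indicates more overlap than chance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import (
    ConfigurationError,
    Direction,
    GeneId,
    GeneSetCollection,
    SignatureTable,
    ValidationError,
)
from .tf_profiling import TfProfile

logger = logging.getLogger("tfsigkit")


def representation_factor(x: int, n: int, D: int, N: int) -> float:
    """Observed / expected overlap of two gene sets in a universe of N.

    Expected overlap of independent draws of sizes n and D is n*D/N,
    so RF = x*N/(n*D).
    """
    if N < 1:
        raise ConfigurationError(f"universe size must be >= 1, got {N}")
    if n < 1 or D < 1:
        raise ValidationError(f"group sizes must be >= 1, got n={n}, D={D}")
    if x < 0 or x > min(n, D):
        raise ValidationError(f"overlap x={x} outside [0, min(n={n}, D={D})]")
    return x * N / (n * D)


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    tf: GeneId
    direction: Direction
    x: int
    n: int
    D: int
    N: int
    rf: float
    p: float | None = None  # optional hypergeometric tail, off by default

    def __post_init__(self):
        if self.x > min(self.n, self.D):
            raise ValidationError(f"{self.set_id}: x={self.x} > min(n, D)")
        if self.n > self.N or self.D > self.N:
            raise ValidationError(f"{self.set_id}: group size exceeds universe")


def enrich_tf_targets(
    target_db: GeneSetCollection,
    signature: SignatureTable,
    universe: list[GeneId],
    with_pvalues: bool = False,
) -> list[EnrichmentRow]:
    """One RF row per (target set, signature direction).

    Target members are intersected with the universe before n is counted,
    and each direction list is likewise restricted to the universe, so
    x <= n <= N holds by construction. Rows come back sorted by RF
    descending, ties by set id then direction.
    """
    universe_syms = {g.symbol for g in universe}
    if not universe_syms:
        raise ConfigurationError("universe is empty")
    outside = signature.symbols() - universe_syms
    if outside:
        logger.warning(
            "enrich_tf_targets: %d signature genes outside the universe "
            "(ignored in overlap counts)", len(outside)
        )
    N = len(universe_syms)
    rows: list[EnrichmentRow] = []
    for direction in (Direction.UP, Direction.DOWN):
        dir_syms = signature.symbols(direction) & universe_syms
        D = len(dir_syms)
        for s in target_db.sets:
            members = s.member_symbols & universe_syms
            n = len(members)
            if n == 0 or D == 0:
                logger.warning(
                    "enrich_tf_targets: skipping %s/%s (n=%d, D=%d undefined RF)",
                    s.set_id, direction.value, n, D,
                )
                continue
            x = len(members & dir_syms)
            p = None
            if with_pvalues:
                p = float(hypergeom.sf(x - 1, N, n, D))
            rows.append(
                EnrichmentRow(
                    set_id=s.set_id,
                    tf=GeneId(target_db.tf_of(s.set_id)),
                    direction=direction,
                    x=x, n=n, D=D, N=N,
                    rf=representation_factor(x, n, D, N),
                    p=p,
                )
            )
    rows.sort(key=lambda r: (-r.rf, r.set_id, r.direction.value))
    logger.info("enrich_tf_targets: %d rows (N=%d)", len(rows), N)
    return rows


def select_enriched(rows: list[EnrichmentRow], threshold: float = 1.0) -> list[EnrichmentRow]:
    """Retain rows with RF strictly above the threshold.

    A TF is considered enriched if any of its experiment sets passes;
    the returned rows keep one entry per passing set.
    """
    kept = [r for r in rows if r.rf > threshold]
    logger.info(
        "select_enriched: %d of %d rows pass rf > %g (%d distinct TFs)",
        len(kept), len(rows), threshold, len({r.tf.symbol for r in kept}),
    )
    return kept


def enriched_tfs(rows: list[EnrichmentRow]) -> list[str]:
    """Distinct TF symbols among enrichment rows, alphabetical."""
    return sorted({r.tf.symbol for r in rows})


def overlap_with_signature_tfs(
    enriched: list[EnrichmentRow], profile: TfProfile
) -> list[GeneId]:
    """TFs that are both target-enriched and themselves in the signature
    TF profile, sorted alphabetically by symbol."""
    enriched_syms = {r.tf.symbol for r in enriched}
    common = sorted(enriched_syms & profile.symbols())
    logger.info("overlap_with_signature_tfs: %d TFs in both lists", len(common))
    return [GeneId(s) for s in common]


@dataclass(frozen=True)
class OraRow:
    category_id: str
    k: int
    K: int
    q: int
    N: int
    p: float
    p_adj: float
    significant: bool


def ora(
    query: list[GeneId],
    categories: GeneSetCollection,
    universe: list[GeneId],
    min_size: int = 2,
    max_size: int = 700,
    alpha: float = 0.05,
) -> list[OraRow]:
    """Hypergeometric overrepresentation analysis with BH-FDR adjustment.

    Categories are restricted to the universe and filtered to the size
    window [min_size, max_size] before testing; p is the upper tail
    P(X >= k) for overlap k between the query (size q) and a category of
    size K in a universe of N genes.
    """
    universe_syms = {g.symbol for g in universe}
    if not universe_syms:
        raise ConfigurationError("universe is empty")
    query_syms = {g.symbol for g in query}
    if not query_syms:
        raise ConfigurationError("query is empty")
    dropped = query_syms - universe_syms
    if dropped:
        logger.warning("ora: dropping %d query genes outside the universe", len(dropped))
        query_syms &= universe_syms
    if not query_syms:
        raise ConfigurationError("no query genes remain inside the universe")
    N, q = len(universe_syms), len(query_syms)

    tested: list[tuple[str, int, int]] = []
    for s in categories.sets:
        members = s.member_symbols & universe_syms
        K = len(members)
        if K < min_size or K > max_size:
            continue
        tested.append((s.set_id, len(members & query_syms), K))
    if not tested:
        return []
    pvals = [float(hypergeom.sf(k - 1, N, K, q)) for _, k, K in tested]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        OraRow(category_id=cid, k=k, K=K, q=q, N=N,
               p=p, p_adj=float(pa), significant=bool(pa <= alpha))
        for (cid, k, K), p, pa in zip(tested, pvals, p_adj)
    ]
    rows.sort(key=lambda r: (r.p, r.category_id))
    logger.info(
        "ora: tested %d of %d categories (size window [%d, %d]); %d significant at %g",
        len(rows), len(categories), min_size, max_size,
        sum(r.significant for r in rows), alpha,
    )
    return rows
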