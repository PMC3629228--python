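"""Expression-weighted gene-set enrichment for miRNA target genes.

Differential miRNA expression is pushed through the target-prediction
scoring matrix onto genes and then onto gene sets:

    g_j = B · |Δx_j|        per-gene regulation for cell line j
    s_j = P · g_j           per-set aggregated regulation

where B is the gene × miRNA scoring matrix, Δx_j the log2 differential
expression of the signature miRNAs in cell line j (missing entries
contribute 0), and P the set × gene indicator matrix.  Per-gene
regulation is averaged across cell lines before scoring.

The enrichment score of a set is the fold-enrichment of mean regulation
among its *targeted* members (genes with nonzero prediction strength for
at least one signature miRNA) relative to the mean over all targeted
genes in the universe; ES > 0 marks enrichment, 0 means no signal.
Coverage significance uses a one-sided Fisher's exact test on the 2×2
table of targeted/untargeted × in-set/out-of-set.  A set is selected when
all three criteria hold: coverage > 10% with at least 3 targeted members,
ES > 1.5, and Fisher p < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import DifferentialTable
from .targets import ScoringMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "load_gene_sets",
    "RegulationStrength",
    "aggregate_regulation",
    "enrichment_scores",
    "fisher_coverage_test",
    "EnrichmentResult",
    "evaluate_gene_sets",
    "select_enriched",
    "format_coverage",
    "results_frame",
]


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a declared gene universe."""

    name: str
    sets: dict[str, list[str]]
    universe: list[str]
    n_dropped_small: int = 0

    def __post_init__(self) -> None:
        self._gene_pos = {g: i for i, g in enumerate(self.universe)}

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def indicator_matrix(self) -> np.ndarray:
        """L × M binary membership matrix P over the universe."""
        P = np.zeros((len(self.sets), len(self.universe)), dtype=np.uint8)
        for li, members in enumerate(self.sets.values()):
            P[li, [self._gene_pos[g] for g in members]] = 1
        return P


def _parse_gmt(lines, source: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{source}, line {ln}: GMT lines need >= 3 tab-separated fields "
                f"(name, description, members...), got {len(fields)}"
            )
        name = fields[0]
        # preserve order, drop duplicate members within the set
        members = list(dict.fromkeys(g for g in fields[2:] if g))
        sets[name] = members
    return sets


def load_gene_sets(
    source,
    universe: list[str],
    min_size: int = 1,
    collection_name: str = "gene_sets",
) -> GeneSetCollection:
    """Read a GMT file and intersect each set with the gene universe.

    ``source`` may be a path or an iterable of lines.  Sets whose
    post-intersection size falls below ``min_size`` are dropped and
    counted (GO-style collections conventionally use ``min_size=15``;
    pathway collections are typically ingested unfiltered).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = _parse_gmt(fh, str(source))
    else:
        raw = _parse_gmt(source, "<lines>")
    in_universe = set(universe)
    kept: dict[str, list[str]] = {}
    dropped = 0
    for name, members in raw.items():
        members = [g for g in members if g in in_universe]
        if len(members) >= min_size:
            kept[name] = members
        else:
            dropped += 1
    if dropped:
        logger.info(
            "%s: dropped %d sets below min_size=%d after universe intersection",
            collection_name, dropped, min_size,
        )
    return GeneSetCollection(collection_name, kept, list(universe), dropped)


@dataclass
class RegulationStrength:
    """Per-gene (g) and per-set (s) regulation, one column per cell line."""

    gene_ids: list[str]
    set_names: list[str]
    cell_line_ids: list[str]
    gene_regulation: np.ndarray  # M × J
    set_regulation: np.ndarray   # L × J

    def mean_gene_regulation(self) -> np.ndarray:
        return self.gene_regulation.mean(axis=1)


def aggregate_regulation(
    scoring: ScoringMatrix,
    delta: DifferentialTable,
    collection: GeneSetCollection,
    signed: bool = False,
) -> RegulationStrength:
    """Map miRNA differential expression onto genes and gene sets.

    ``delta`` should already be restricted to the signature miRNAs; its
    rows are aligned to the scoring matrix columns by id (an empty
    intersection is an error).  Missing Δx entries contribute 0.  By
    default the magnitude |Δx| is aggregated so up- and down-regulated
    miRNAs combine in one statistic; ``signed=True`` keeps the sign for
    directional splits.
    """
    if collection.universe != scoring.gene_ids:
        raise ValueError("gene axis mismatch: collection universe != scoring genes")
    common = [m for m in scoring.mirna_ids if m in set(delta.mirna_ids)]
    if not common:
        raise ValueError("miRNA axis mismatch: no shared miRNAs between B and Δx")
    if len(common) < len(scoring.mirna_ids):
        logger.info(
            "aggregating over %d of %d scoring-matrix miRNAs present in Δx",
            len(common), len(scoring.mirna_ids),
        )
    bpos = {m: j for j, m in enumerate(scoring.mirna_ids)}
    B = scoring.b[:, [bpos[m] for m in common]]
    dx = delta.restrict(common).delta_x.copy()
    dx = np.nan_to_num(dx, nan=0.0)
    if not signed:
        dx = np.abs(dx)
    g = B @ dx                                  # M × J
    s = collection.indicator_matrix() @ g       # L × J
    return RegulationStrength(
        list(scoring.gene_ids), collection.set_names,
        list(delta.cell_line_ids), g, s,
    )


def enrichment_scores(
    strength: RegulationStrength,
    targeted: np.ndarray,
    collection: GeneSetCollection,
    combine: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-enrichment of mean per-targeted-gene regulation, per set.

    ES_l = mean(ḡ over targeted members of set l) / mean(ḡ over all
    targeted genes), with ḡ the per-gene regulation combined across cell
    lines (``combine`` = 'mean' or 'max').  Sets without targeted members
    get ES 0 and a raised no-signal flag.

    Returns (es, no_signal) arrays aligned with ``collection.set_names``.
    """
    targeted = np.asarray(targeted, dtype=bool)
    if targeted.shape != (len(strength.gene_ids),):
        raise ValueError("targeted mask must align with the gene universe")
    if not targeted.any():
        raise ValueError("no targeted gene in the universe")
    if combine == "mean":
        gbar = strength.gene_regulation.mean(axis=1)
    elif combine == "max":
        gbar = strength.gene_regulation.max(axis=1)
    else:
        raise ValueError("combine must be 'mean' or 'max'")
    denom = gbar[targeted].mean()
    if denom == 0.0:
        raise ValueError("zero genome-wide regulation: no differential signal")
    P = collection.indicator_matrix().astype(bool)
    es = np.zeros(P.shape[0])
    no_signal = np.zeros(P.shape[0], dtype=bool)
    for li in range(P.shape[0]):
        members = P[li] & targeted
        if members.any():
            es[li] = gbar[members].mean() / denom
        else:
            no_signal[li] = True
    return es, no_signal


def fisher_coverage_test(m_l: int, n_l: int, m_total: int, M: int) -> float:
    """One-sided Fisher's exact p for targeted-gene over-representation.

    Tests the 2×2 table [[m_l, n_l − m_l], [m_total − m_l,
    M − n_l − m_total + m_l]] against over-representation, i.e. the upper
    hypergeometric tail P(X ≥ m_l) with M genes, m_total targeted, n_l
    drawn.
    """
    if min(m_l, n_l, m_total, M) < 0:
        raise ValueError("all counts must be non-negative")
    if m_l > min(n_l, m_total) or n_l > M or m_total > M:
        raise ValueError(
            f"inconsistent margins: m_l={m_l}, n_l={n_l}, m_total={m_total}, M={M}"
        )
    return float(hypergeom.sf(m_l - 1, M, m_total, n_l))


@dataclass
class EnrichmentResult:
    """Per-set coverage, enrichment score, Fisher p and criterion flags."""

    name: str
    size: int
    targeted: int
    coverage: float
    es: float
    no_signal: bool
    p: float
    passes_coverage: bool = field(default=False)
    passes_es: bool = field(default=False)
    passes_p: bool = field(default=False)

    @property
    def passes(self) -> bool:
        return self.passes_coverage and self.passes_es and self.passes_p


def evaluate_gene_sets(
    scoring: ScoringMatrix,
    delta: DifferentialTable,
    collection: GeneSetCollection,
    signed: bool = False,
    combine: str = "mean",
    es_min: float = 1.5,
    p_max: float = 0.01,
    min_coverage: float = 0.10,
    min_genes: int = 3,
) -> list[EnrichmentResult]:
    """Full per-set evaluation: coverage, ES, Fisher p, criterion flags."""
    strength = aggregate_regulation(scoring, delta, collection, signed=signed)
    targeted = scoring.targeted_genes
    es, no_signal = enrichment_scores(strength, targeted, collection, combine=combine)
    m_total = int(targeted.sum())
    M = len(scoring.gene_ids)
    P = collection.indicator_matrix().astype(bool)
    results = []
    for li, name in enumerate(collection.set_names):
        n_l = int(P[li].sum())
        m_l = int((P[li] & targeted).sum())
        coverage = m_l / n_l
        p = fisher_coverage_test(m_l, n_l, m_total, M)
        results.append(
            EnrichmentResult(
                name=name, size=n_l, targeted=m_l, coverage=coverage,
                es=float(es[li]), no_signal=bool(no_signal[li]), p=p,
                passes_coverage=(coverage > min_coverage) and (m_l >= min_genes),
                passes_es=es[li] > es_min,
                passes_p=p < p_max,
            )
        )
    return results


def select_enriched(
    results: list[EnrichmentResult],
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Split evaluated sets into selected and near-miss lists.

    Selected sets pass all three criteria and are ranked by ES descending
    (ties: p ascending, then name).  Near-misses pass the ES and p
    criteria but fail the coverage/minimum-gene criterion — biologically
    notable regulation too sparse to select.
    """
    passing = sorted(
        (r for r in results if r.passes),
        key=lambda r: (-r.es, r.p, r.name),
    )
    near_miss = sorted(
        (r for r in results if r.passes_es and r.passes_p and not r.passes_coverage),
        key=lambda r: (-r.es, r.p, r.name),
    )
    return passing, near_miss


def format_coverage(m_l: int, n_l: int, style: str = "integer") -> str:
    """Render a targeted-gene percentage the way result tables print it.

    'integer' rounds to a whole percent (pathway-table convention);
    'one_decimal' keeps one decimal place (GO-table convention).
    """
    pct = 100.0 * m_l / n_l
    if style == "integer":
        return f"{pct:.0f}%"
    if style == "one_decimal":
        return f"{pct:.1f}%"
    raise ValueError("style must be 'integer' or 'one_decimal'")


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.name,
                "size": r.size,
                "targeted": r.targeted,
                "coverage_pct": round(100 * r.coverage, 4),
                "es": round(r.es, 6),
                "no_signal": r.no_signal,
                "p": f"{r.p:.6g}",
                "passes_coverage": r.passes_coverage,
                "passes_es": r.passes_es,
                "passes_p": r.passes_p,
                "passes": r.passes,
            }
            for r in results
        ]
    )
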